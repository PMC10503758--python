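surface_form,concept_id,name,semantic_type
abd pain,C0000737,abdominal pain,Sign or Symptom
abdominal pain,C0000737,abdominal pain,Sign or Symptom
nausea,C0027497,nausea,Sign or Symptom
vomiting,C0042963,vomiting,Sign or Symptom
headache,C0018681,headache,Sign or Symptom
dizziness,C0012833,dizziness,Sign or Symptom
chest pain,C0008031,chest pain,Sign or Symptom
back pain,C0004604,back pain,Sign or Symptom
shortness of breath,C0013404,dyspnea,Sign or Symptom
altered mental status,C0856054,altered mental status,Sign or Symptom
opioid overdose,C4324621,opioid overdose,Injury or Poisoning
heroin overdose,C0413252,heroin overdose,Injury or Poisoning
fall,C0000921,accidental fall,Injury or Poisoning
laceration,C0043246,laceration,Injury or Poisoning
opioid use disorder,C4324337,opioid use disorder,Mental or Behavioral Dysfunction
opioid withdrawal,C0029104,opioid withdrawal,Mental or Behavioral Dysfunction
alcohol use disorder,C0001973,alcohol use disorder,Mental or Behavioral Dysfunction
depression,C0011570,depression,Mental or Behavioral Dysfunction
anxiety,C0003467,anxiety,Mental or Behavioral Dysfunction
suicidal ideation,C0424000,suicidal ideation,Mental or Behavioral Dysfunction
agitation,C0085631,agitation,Mental or Behavioral Dysfunction
psychosis,C0033975,psychotic disorder,Mental or Behavioral Dysfunction
hypertension,C0020538,hypertension,Disease or Syndrome
diabetes mellitus,C0011849,diabetes mellitus,Disease or Syndrome
congestive heart failure,C0018802,congestive heart failure,Disease or Syndrome
copd,C0024117,chronic obstructive pulmonary disease,Disease or Syndrome
cirrhosis,C0023890,cirrhosis of liver,Disease or Syndrome
cellulitis,C0007642,cellulitis,Disease or Syndrome
pneumonia,C0032285,pneumonia,Disease or Syndrome
kidney stone,C0022650,kidney stone,Disease or Syndrome
sepsis,C0243026,sepsis,Disease or Syndrome
hiv infection,C0019693,HIV infection,Disease or Syndrome
endocarditis,C0014118,endocarditis,Disease or Syndrome
dementia,C0011265,dementia,Disease or Syndrome
withdrawal seizure,C0149967,withdrawal seizure,Disease or Syndrome
psychiatric evaluation,C0846574,psychiatric evaluation,Diagnostic Procedure
urine drug screen,C0430379,urine drug screen,Laboratory Procedure
blood culture,C0200949,blood culture,Laboratory Procedure
ct head,C0412585,CT of head,Diagnostic Procedure
wound repair,C0043241,wound repair,Therapeutic or Preventive Procedure
intubation,C0021925,intubation,Therapeutic or Preventive Procedure
joint replacement,C0185303,joint replacement,Therapeutic or Preventive Procedure
dialysis,C0011946,dialysis,Therapeutic or Preventive Procedure
naloxone,C0027358,naloxone,Pharmacologic Substance
methadone,C0025605,methadone,Pharmacologic Substance
buprenorphine,C0006405,buprenorphine,Pharmacologic Substance
fentanyl,C0015846,fentanyl,Pharmacologic Substance
heroin,C0011892,heroin,Pharmacologic Substance
insulin,C0021641,insulin,Pharmacologic Substance
lorazepam,C0024002,lorazepam,Pharmacologic Substance
acetaminophen oral tablet,C0979059,acetaminophen oral tablet,Clinical Drug
oxycodone 5 mg tablet,C0978821,oxycodone 5 mg oral tablet,Clinical Drug
liver,C0023884,liver,"Body Part, Organ, or Organ Component"
kidney,C0022646,kidney,"Body Part, Organ, or Organ Component"
spine,C0037949,spine,"Body Part, Organ, or Organ Component"
homelessness,C0237154,homelessness,Finding
tobacco use,C0543414,tobacco use,Finding
weakness,C3714552,weakness,Finding
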