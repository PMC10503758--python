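# Default UMLS semantic-type allow-list for concept filtering.
# Covers disorders, findings, procedures, chemicals/drugs and anatomy;
# edit to taste — anything not listed is dropped after extraction.
semantic_types:
  - Disease or Syndrome
  - Mental or Behavioral Dysfunction
  - Sign or Symptom
  - Finding
  - Injury or Poisoning
  - Therapeutic or Preventive Procedure
  - Diagnostic Procedure
  - Laboratory Procedure
  - Pharmacologic Substance
  - Clinical Drug
  - Body Part, Organ, or Organ Component
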