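"""Two-cohort synthetic EHR generator with planted ground truth.

Emulates the statistical structure the phenotyping pipeline assumes: an
"opioid" cohort whose notes are mixtures over planted topics with
cluster-conditional topic profiles and outcome rates, and a demographically
matched background ED cohort drawn from its own topic profile. Both cohorts
share a block of common (template/jargon) words so the ubiquity filter has
work to do, and a block of neutral words present at equal rates so the
chi-square contrast has work to do.

Generative model, per opioid encounter:

    cluster  c ~ Categorical(cluster_probs)
    theta      ~ Dirichlet(concentration * cluster_topic_profiles[c])
    length   L ~ NegBin(mean, dispersion), floored at 1
    token_i    : topic ~ Categorical(theta), word ~ Categorical(phi_topic)

Background encounters draw all tokens from a single background word
distribution, and their demographics are resampled from the opioid cohort's
empirical distribution (matching on age / sex / race). Lab values are
cohort-specific normals; death times are exponential with cluster-specific
hazards, administratively censored at 730 days after discharge; ED-return
and medication outcomes are cluster-conditional Bernoulli draws. All dates
are ISO-8601 and all interval arithmetic is in integer days. A fixed seed
reproduces the dataset byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ClusterOutcomeParams",
    "LabSpec",
    "DiagnosisSpec",
    "SimulationConfig",
    "SyntheticDataset",
    "default_config",
    "generate_dataset",
    "summarize_truth",
    "token_corpus",
    "outcome_records",
    "write_dataset",
    "read_dataset",
]

STUDY_START = date(2013, 3, 1)
FOLLOWUP_DAYS = 730  # administrative censoring horizon after discharge

_FILLER = ["the", "patient", "reports", "today", "states", "arrived", "seen",
           "stable", "denies", "history"]


@dataclass
class ClusterOutcomeParams:
    """Outcome-generating parameters for one planted cluster."""

    death_hazard_per_day: float
    p_return_6m: float
    p_return_12m: float
    p_opioid_return_6m: float
    p_opioid_return_12m: float
    p_buprenorphine: float
    p_methadone: float
    p_naloxone: float

    def validate(self) -> None:
        if self.death_hazard_per_day < 0:
            raise ValueError("death hazard must be >= 0")
        for name in ("p_return_6m", "p_return_12m", "p_opioid_return_6m",
                     "p_opioid_return_12m", "p_buprenorphine", "p_methadone",
                     "p_naloxone"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.p_return_6m > self.p_return_12m:
            raise ValueError("6-month return probability exceeds 12-month")
        if self.p_opioid_return_6m > self.p_opioid_return_12m:
            raise ValueError("6-month opioid return probability exceeds 12-month")


@dataclass
class LabSpec:
    """Background mean/SD and additive opioid-cohort shift for one lab."""

    name: str
    background_mean: float
    background_sd: float
    opioid_shift: float


@dataclass
class DiagnosisSpec:
    """One ICD-10 code with cluster-conditional and background prevalences."""

    code: str
    group: str
    cluster_prevalence: list[float]
    background_prevalence: float


@dataclass
class SimulationConfig:
    n_opioid_encounters: int = 2000
    n_background_encounters: int = 2000
    n_true_topics: int = 5
    n_true_clusters: int = 4
    vocab_size: int = 200
    doc_length_mean: float = 100.0
    doc_length_dispersion: float = 10.0
    dirichlet_alpha_true: float = 25.0  # total Dirichlet concentration around the profile
    cluster_topic_profiles: list[list[float]] | None = None
    cluster_probs: list[float] | None = None
    lab_catalog: list[LabSpec] = field(default_factory=list)
    lab_measure_prob: float = 0.6
    outcome_params: list[ClusterOutcomeParams] = field(default_factory=list)
    icd10_pool: list[DiagnosisSpec] = field(default_factory=list)
    render_text: bool = False
    filler_rate: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.cluster_topic_profiles is None:
            self.cluster_topic_profiles = _default_profiles(
                self.n_true_clusters, self.n_true_topics
            )
        if self.cluster_probs is None:
            self.cluster_probs = [1.0 / self.n_true_clusters] * self.n_true_clusters
        if not self.lab_catalog:
            self.lab_catalog = _default_labs()
        if not self.outcome_params:
            self.outcome_params = _default_outcomes(self.n_true_clusters)
        if not self.icd10_pool:
            self.icd10_pool = _default_diagnoses(self.n_true_clusters)

    def validate(self) -> None:
        if min(self.n_true_topics, self.n_true_clusters, self.vocab_size) < 1:
            raise ValueError("topic, cluster and vocabulary counts must be >= 1")
        if self.n_opioid_encounters < 0 or self.n_background_encounters < 0:
            raise ValueError("encounter counts must be non-negative")
        profiles = np.asarray(self.cluster_topic_profiles, dtype=float)
        if profiles.shape != (self.n_true_clusters, self.n_true_topics):
            raise ValueError("cluster_topic_profiles must be C x K")
        if (profiles < 0).any() or np.abs(profiles.sum(axis=1) - 1).max() > 1e-9:
            raise ValueError("each cluster topic profile must be a simplex row")
        probs = np.asarray(self.cluster_probs, dtype=float)
        if len(probs) != self.n_true_clusters or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("cluster_probs must sum to 1 over the clusters")
        if len(self.outcome_params) != self.n_true_clusters:
            raise ValueError("need outcome parameters for every cluster")
        for op in self.outcome_params:
            op.validate()
        for dx in self.icd10_pool:
            if len(dx.cluster_prevalence) != self.n_true_clusters:
                raise ValueError(f"{dx.code}: prevalence list must cover every cluster")
            for p in [*dx.cluster_prevalence, dx.background_prevalence]:
                if not 0 <= p <= 1:
                    raise ValueError(f"{dx.code}: prevalence {p} outside [0, 1]")
        if not 0 < self.lab_measure_prob <= 1:
            raise ValueError("lab_measure_prob must be in (0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        doc = yaml.safe_load(Path(path).read_text())
        doc["lab_catalog"] = [LabSpec(**d) for d in doc.get("lab_catalog", [])]
        doc["outcome_params"] = [ClusterOutcomeParams(**d) for d in doc.get("outcome_params", [])]
        doc["icd10_pool"] = [DiagnosisSpec(**d) for d in doc.get("icd10_pool", [])]
        return cls(**doc)


def _default_profiles(C: int, K: int) -> list[list[float]]:
    """Well-separated cluster topic profiles.

    Each cluster concentrates 80% of its mass on its own dominant topic
    (cluster c -> topic c, cycling when C > K); the remaining 20% is spread
    over every topic, so topics beyond the first C are weak shared
    components rather than being coupled to a single cluster. Keeping each
    topic either cluster-specific or shared keeps all planted topics
    statistically identifiable from the documents.
    """
    profiles = np.full((C, K), 0.2 / K)
    for c in range(C):
        profiles[c, c % K] += 0.8
    profiles /= profiles.sum(axis=1, keepdims=True)
    return profiles.tolist()


def _default_labs() -> list[LabSpec]:
    return [
        LabSpec("sodium", 140.0, 3.0, -1.0),
        LabSpec("creatinine", 1.0, 0.3, 0.2),
        LabSpec("wbc", 7.5, 2.0, 1.0),
        LabSpec("pao2", 90.0, 10.0, -5.0),
        LabSpec("lactate", 1.2, 0.5, 0.3),
    ]


def _default_outcomes(C: int) -> list[ClusterOutcomeParams]:
    """Cluster-conditional outcome rates spanning realistic ED ranges:
    one-year survival roughly 85-96%, 12-month all-cause returns 9-34%,
    opioid returns 8-17%, MOUD prescriptions 17-43%."""
    base = [
        ClusterOutcomeParams(1.0e-4, 0.10, 0.18, 0.06, 0.10, 0.10, 0.20, 0.08),
        ClusterOutcomeParams(1.5e-4, 0.20, 0.30, 0.08, 0.13, 0.15, 0.30, 0.12),
        ClusterOutcomeParams(4.5e-4, 0.06, 0.09, 0.05, 0.08, 0.05, 0.17, 0.16),
        ClusterOutcomeParams(2.5e-4, 0.25, 0.34, 0.10, 0.17, 0.20, 0.43, 0.10),
    ]
    return [base[c % len(base)] for c in range(C)]


def _default_diagnoses(C: int) -> list[DiagnosisSpec]:
    def per_cluster(vals):
        return [vals[c % len(vals)] for c in range(C)]

    return [
        DiagnosisSpec("F1120", "opioid_dependence", per_cluster([0.9, 0.9, 0.9, 0.9]), 0.0),
        DiagnosisSpec("F1020", "alcohol_use_disorder", per_cluster([0.20, 0.50, 0.30, 0.25]), 0.10),
        DiagnosisSpec("F329", "mood_disorder", per_cluster([0.50, 0.70, 0.55, 0.60]), 0.20),
        DiagnosisSpec("I509", "heart_failure", per_cluster([0.05, 0.05, 0.35, 0.10]), 0.05),
        DiagnosisSpec("E119", "diabetes", per_cluster([0.10, 0.10, 0.30, 0.15]), 0.10),
        DiagnosisSpec("N189", "chronic_kidney_disease", per_cluster([0.03, 0.03, 0.25, 0.05]), 0.03),
        DiagnosisSpec("C799", "metastatic_cancer", per_cluster([0.01, 0.01, 0.08, 0.02]), 0.01),
        DiagnosisSpec("F03", "dementia", per_cluster([0.02, 0.02, 0.20, 0.03]), 0.02),
        DiagnosisSpec("K7030", "cirrhosis", per_cluster([0.03, 0.10, 0.08, 0.05]), 0.02),
        DiagnosisSpec("B20", "hiv", per_cluster([0.03, 0.05, 0.04, 0.08]), 0.01),
    ]


def default_config(**overrides) -> SimulationConfig:
    return SimulationConfig(**overrides)


@dataclass
class SyntheticDataset:
    encounters: pd.DataFrame
    notes: list[dict]
    diagnoses: pd.DataFrame
    labs: pd.DataFrame
    medications: pd.DataFrame
    outcomes: pd.DataFrame
    truth: dict

    def opioid_ids(self) -> list[str]:
        mask = self.encounters["cohort"] == "opioid"
        return self.encounters.loc[mask, "encounter_id"].tolist()


def _build_vocabulary(cfg: SimulationConfig) -> tuple[list[str], np.ndarray, np.ndarray, dict]:
    """Planted word distributions.

    Returns (words, phi [K x V], phi_background [V], layout). The vocabulary
    is partitioned into common words (high mass in every distribution),
    neutral words (equal low-rate presence in both cohorts), one block per
    planted topic, and a background block.
    """
    V, K = cfg.vocab_size, cfg.n_true_topics
    n_common = max(2, V // 20)
    n_neutral = max(2, V // 10)
    n_blocks = K + 1
    block_pool = V - n_common - n_neutral
    if block_pool < n_blocks:
        raise ValueError(f"vocab_size={V} too small for {K} topics plus background")
    words = [f"w{i:04d}" for i in range(V)]
    if cfg.render_text:
        from .concept_extraction import default_lexicon_path, load_lexicon

        lex = load_lexicon(default_lexicon_path())
        forms = sorted(lex.entries)
        if V > len(forms):
            raise ValueError(
                f"render_text requires vocab_size <= {len(forms)} lexicon surface forms"
            )
        words = forms[:V]
    common = np.arange(n_common)
    neutral = np.arange(n_common, n_common + n_neutral)
    blocks = np.array_split(np.arange(n_common + n_neutral, V), n_blocks)
    phi = np.zeros((K, V))
    for k in range(K):
        phi[k, common] = 0.12 / n_common
        phi[k, neutral] = 0.06 / n_neutral
        phi[k, blocks[k]] = 0.80 / len(blocks[k])
        other = np.setdiff1d(np.arange(V), np.concatenate([common, neutral, blocks[k]]))
        phi[k, other] = 0.02 / len(other)
        phi[k] /= phi[k].sum()
    phi_bg = np.zeros(V)
    phi_bg[common] = 0.12 / n_common
    phi_bg[neutral] = 0.06 / n_neutral
    phi_bg[blocks[K]] = 0.80 / len(blocks[K])
    other = np.setdiff1d(np.arange(V), np.concatenate([common, neutral, blocks[K]]))
    phi_bg[other] = 0.02 / len(other)
    phi_bg /= phi_bg.sum()
    layout = {
        "common": common.tolist(),
        "neutral": neutral.tolist(),
        "topic_blocks": [b.tolist() for b in blocks[:K]],
        "background_block": blocks[K].tolist(),
    }
    return words, phi, phi_bg, layout


def _doc_length(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    r = cfg.doc_length_dispersion
    p = r / (r + cfg.doc_length_mean)
    return max(1, int(rng.negative_binomial(r, p)))


def _demographics(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Marginal demographics resembling an adult ED opioid cohort."""
    age = np.clip(np.round(rng.normal(48, 14, size=n)), 18, 95).astype(int)
    sex = rng.choice(["Male", "Female", "Unknown"], size=n, p=[0.54, 0.455, 0.005])
    race = rng.choice(
        ["White", "Black", "Asian", "Other"], size=n, p=[0.65, 0.21, 0.003, 0.137]
    )
    ethnicity = rng.choice(["Hispanic", "Non-Hispanic", "Unknown"], size=n,
                           p=[0.175, 0.821, 0.004])
    insurance = rng.choice(
        ["Medicaid", "Medicare", "Managed Care", "BCBS", "Other"],
        size=n, p=[0.553, 0.252, 0.075, 0.046, 0.074],
    )
    esi = rng.choice([1, 2, 3, 4, 5], size=n, p=[0.014, 0.40, 0.444, 0.12, 0.022])
    disposition = rng.choice(["discharge", "admit", "other"], size=n,
                             p=[0.534, 0.414, 0.052])
    return pd.DataFrame(
        {"age": age, "sex": sex, "race": race, "ethnicity": ethnicity,
         "insurance": insurance, "esi": esi, "disposition": disposition}
    )


def _render_text(rng: np.random.Generator, tokens: list[str], filler_rate: float) -> str:
    pieces = []
    for tok in tokens:
        if rng.random() < filler_rate:
            pieces.append(_FILLER[rng.integers(0, len(_FILLER))])
        pieces.append(tok)
    return " ".join(pieces)


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw a complete two-cohort synthetic dataset plus its truth manifest."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    words, phi, phi_bg, layout = _build_vocabulary(config)
    C, K = config.n_true_clusters, config.n_true_topics
    profiles = np.asarray(config.cluster_topic_profiles, dtype=float)

    n_op, n_bg = config.n_opioid_encounters, config.n_background_encounters
    op_ids = [f"OP{i:06d}" for i in range(n_op)]
    bg_ids = [f"BG{i:06d}" for i in range(n_bg)]

    demo_op = _demographics(rng, n_op)
    if n_op > 0 and n_bg > 0:
        # matched background: resample age/sex/race jointly from the opioid cohort
        pick = rng.integers(0, n_op, size=n_bg)
        demo_bg = _demographics(rng, n_bg)
        for col in ("age", "sex", "race"):
            demo_bg[col] = demo_op[col].to_numpy()[pick]
    else:
        demo_bg = _demographics(rng, n_bg)

    arrival_op = [STUDY_START + timedelta(days=int(d))
                  for d in rng.integers(0, 1800, size=n_op)]
    arrival_bg = [STUDY_START + timedelta(days=int(d))
                  for d in rng.integers(0, 1800, size=n_bg)]

    clusters = rng.choice(C, size=n_op, p=np.asarray(config.cluster_probs)) if n_op else (
        np.zeros(0, dtype=int)
    )
    conc = config.dirichlet_alpha_true
    thetas = np.zeros((n_op, K))
    notes: list[dict] = []

    def _emit_notes(eid: str, token_ids: np.ndarray) -> None:
        toks = [words[w] for w in token_ids]
        if len(toks) > 3 and rng.random() < 0.5:
            cut = len(toks) * 7 // 10
            parts = [("provider", toks[:cut]), ("nursing", toks[cut:])]
        else:
            parts = [("provider", toks)]
        for note_type, part in parts:
            rec = {"encounter_id": eid, "note_type": note_type, "tokens": part}
            if config.render_text:
                rec["text"] = _render_text(rng, part, config.filler_rate)
            notes.append(rec)

    for i, eid in enumerate(op_ids):
        c = clusters[i]
        theta = rng.dirichlet(conc * profiles[c] + 1e-6)
        thetas[i] = theta
        L = _doc_length(rng, config)
        z = rng.choice(K, size=L, p=theta)
        per_topic = np.bincount(z, minlength=K)
        parts = [
            rng.choice(config.vocab_size, size=int(per_topic[k]), p=phi[k])
            for k in range(K) if per_topic[k]
        ]
        token_ids = np.concatenate(parts) if parts else np.zeros(0, dtype=int)
        _emit_notes(eid, token_ids.astype(int))

    for eid in bg_ids:
        L = _doc_length(rng, config)
        token_ids = rng.choice(config.vocab_size, size=L, p=phi_bg)
        _emit_notes(eid, np.asarray(token_ids, dtype=int))

    encounters = pd.concat(
        [
            pd.DataFrame({"encounter_id": op_ids, "cohort": "opioid"}).join(demo_op),
            pd.DataFrame({"encounter_id": bg_ids, "cohort": "background"}).join(demo_bg),
        ],
        ignore_index=True,
    )
    encounters["patient_id"] = ["P" + e for e in encounters["encounter_id"]]
    encounters["arrival_date"] = [d.isoformat() for d in arrival_op + arrival_bg]

    # structured diagnoses
    dx_rows = []
    for i, eid in enumerate(op_ids):
        for dx in config.icd10_pool:
            if rng.random() < dx.cluster_prevalence[clusters[i]]:
                dx_rows.append((eid, dx.code, dx.group))
    for eid in bg_ids:
        for dx in config.icd10_pool:
            if rng.random() < dx.background_prevalence:
                dx_rows.append((eid, dx.code, dx.group))
    diagnoses = pd.DataFrame(dx_rows, columns=["encounter_id", "icd10", "group"])

    # continuous labs with cohort-specific means
    lab_rows = []
    for eid, is_op in [(e, True) for e in op_ids] + [(e, False) for e in bg_ids]:
        for lab in config.lab_catalog:
            if rng.random() < config.lab_measure_prob:
                mu = lab.background_mean + (lab.opioid_shift if is_op else 0.0)
                lab_rows.append((eid, lab.name, float(rng.normal(mu, lab.background_sd))))
    labs = pd.DataFrame(lab_rows, columns=["encounter_id", "lab_name", "value"])

    # outcomes for the opioid cohort
    out_rows = []
    med_rows = []
    for i, eid in enumerate(op_ids):
        c = clusters[i]
        op = config.outcome_params[c]
        discharge = arrival_op[i] + timedelta(days=1)
        if op.death_hazard_per_day > 0:
            t_death = int(np.ceil(rng.exponential(1.0 / op.death_hazard_per_day)))
        else:
            t_death = FOLLOWUP_DAYS + 1
        death = int(t_death <= FOLLOWUP_DAYS)
        followup = min(t_death, FOLLOWUP_DAYS)
        death_date = (discharge + timedelta(days=t_death)).isoformat() if death else ""

        def _returns(p6, p12):
            u = rng.random()
            if u < p6:
                return [int(rng.integers(1, 184))]
            if u < p12:
                return [int(rng.integers(184, 366))]
            return []

        ret = _returns(op.p_return_6m, op.p_return_12m)
        op_ret = _returns(op.p_opioid_return_6m, op.p_opioid_return_12m)
        bup = int(rng.random() < op.p_buprenorphine)
        met = int(rng.random() < op.p_methadone)
        nal = int(rng.random() < op.p_naloxone)
        for flag, drug in ((bup, "buprenorphine"), (met, "methadone"), (nal, "naloxone")):
            if flag:
                med_rows.append((eid, drug))
        out_rows.append(
            {
                "encounter_id": eid,
                "discharge_date": discharge.isoformat(),
                "death_date": death_date,
                "censor_date": (discharge + timedelta(days=FOLLOWUP_DAYS)).isoformat(),
                "followup_days": followup,
                "death": death,
                "return_days": json.dumps(ret),
                "opioid_return_days": json.dumps(op_ret),
                "buprenorphine_rx": bup,
                "methadone_rx": met,
                "naloxone_rx": nal,
            }
        )
    outcomes = pd.DataFrame(
        out_rows,
        columns=[
            "encounter_id", "discharge_date", "death_date", "censor_date",
            "followup_days", "death", "return_days", "opioid_return_days",
            "buprenorphine_rx", "methadone_rx", "naloxone_rx",
        ],
    )
    medications = pd.DataFrame(med_rows, columns=["encounter_id", "drug"])

    truth = {
        "vocabulary": words,
        "phi": phi.tolist(),
        "background_phi": phi_bg.tolist(),
        "vocab_layout": layout,
        "encounter_ids": op_ids,
        "theta": thetas.tolist(),
        "cluster": [int(c) for c in clusters],
        "cluster_topic_profiles": profiles.tolist(),
        "seed": config.seed,
    }
    return SyntheticDataset(
        encounters=encounters, notes=notes, diagnoses=diagnoses, labs=labs,
        medications=medications, outcomes=outcomes, truth=truth,
    )


def token_corpus(dataset: SyntheticDataset, vocabulary: list[str] | None = None):
    """Term-frequency corpus over the opioid cohort's raw note tokens.

    Bypasses extraction and the vocabulary filters — the direct input for
    planted-topic recovery experiments. The vocabulary defaults to the
    planted one so fitted topics align with the truth manifest columns.
    """
    from .corpus_builder import build_corpus, combine_encounter_tokens

    by_enc: dict[str, list[list[str]]] = {}
    for rec in dataset.notes:
        by_enc.setdefault(rec["encounter_id"], []).append(rec["tokens"])
    bags = [
        combine_encounter_tokens(by_enc.get(eid, []), encounter_id=eid)
        for eid in dataset.opioid_ids()
    ]
    return build_corpus(bags, vocabulary or dataset.truth["vocabulary"])


def outcome_records(dataset: SyntheticDataset) -> pd.DataFrame:
    """Outcome table in the analysis-ready form used by the outcomes module
    (day-offset return lists decoded, diagnosis codes attached)."""
    out = dataset.outcomes.copy()
    if out.empty:
        return out.assign(diagnosis_codes=pd.Series(dtype=object))
    out["return_days"] = out["return_days"].apply(json.loads)
    out["opioid_return_days"] = out["opioid_return_days"].apply(json.loads)
    codes = dataset.diagnoses.groupby("encounter_id")["icd10"].apply(list)
    out["diagnosis_codes"] = out["encounter_id"].map(codes).apply(
        lambda v: v if isinstance(v, list) else []
    )
    return out


def summarize_truth(dataset: SyntheticDataset) -> pd.DataFrame:
    """Per-planted-cluster counts, mean true theta, and empirical outcome rates."""
    if not dataset.truth or "cluster" not in dataset.truth:
        raise ValueError("dataset has no truth manifest")
    clusters = np.asarray(dataset.truth["cluster"], dtype=int)
    if clusters.size == 0:
        return pd.DataFrame()
    theta = np.asarray(dataset.truth["theta"], dtype=float)
    recs = outcome_records(dataset)
    recs = recs.set_index("encounter_id").loc[dataset.truth["encounter_ids"]]
    rows = []
    for c in sorted(set(clusters.tolist())):
        mask = clusters == c
        g = recs[mask]
        row = {
            "cluster": c,
            "n": int(mask.sum()),
            "mean_theta": theta[mask].mean(axis=0).round(6).tolist(),
            "death_365d": float((
                (g["death"] == 1) & (g["followup_days"] <= 365)
            ).mean()),
            "return_183d": float(g["return_days"].apply(
                lambda d: any(0 < x <= 183 for x in d)).mean()),
            "return_365d": float(g["return_days"].apply(
                lambda d: any(0 < x <= 365 for x in d)).mean()),
            "opioid_return_365d": float(g["opioid_return_days"].apply(
                lambda d: any(0 < x <= 365 for x in d)).mean()),
            "buprenorphine": float(g["buprenorphine_rx"].mean()),
            "methadone": float(g["methadone_rx"].mean()),
            "naloxone": float(g["naloxone_rx"].mean()),
        }
        rows.append(row)
    return pd.DataFrame(rows)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.encounters.to_csv(outdir / "encounters.csv", index=False)
    dataset.diagnoses.to_csv(outdir / "diagnoses.csv", index=False)
    dataset.labs.to_csv(outdir / "labs.csv", index=False)
    dataset.medications.to_csv(outdir / "medications.csv", index=False)
    dataset.outcomes.to_csv(outdir / "outcomes.csv", index=False)
    with open(outdir / "notes.jsonl", "w") as fh:
        for rec in dataset.notes:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    (outdir / "truth.json").write_text(json.dumps(dataset.truth))


def read_dataset(indir: str | Path) -> SyntheticDataset:
    indir = Path(indir)
    notes = []
    with open(indir / "notes.jsonl") as fh:
        for line in fh:
            if line.strip():
                notes.append(json.loads(line))
    return SyntheticDataset(
        encounters=pd.read_csv(indir / "encounters.csv"),
        notes=notes,
        diagnoses=pd.read_csv(indir / "diagnoses.csv"),
        labs=pd.read_csv(indir / "labs.csv"),
        medications=pd.read_csv(indir / "medications.csv"),
        outcomes=pd.read_csv(
            indir / "outcomes.csv",
            dtype={"death_date": str},
            keep_default_na=False,
            na_values=[],
        ),
        truth=json.loads((indir / "truth.json").read_text()),
    )
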