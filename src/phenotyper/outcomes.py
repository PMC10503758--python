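"""Cluster-level outcome profiling.

For each discovered phenotype cluster this module computes the external
validity metrics used to characterize it:

* Kaplan-Meier survival after the index ED discharge (product-limit
  estimator; survival at 365 days reported, curve retained for plotting);
* Charlson comorbidity index (CCI) from ICD-10 codes using the Quan (2005)
  coding algorithm with the original Charlson weights, shipped as an
  editable CSV;
* 6-month (183-day) and 12-month (365-day) all-cause and opioid-related ED
  return rates, inclusive right boundary;
* outpatient buprenorphine / methadone / naloxone prescription rates;
* relative risk (RR) of each structured variable: the within-cluster rate
  divided by the rate among all remaining encounters,
  RR = (a / n_c) / ((A - a) / (N - n_c));
* chi-square rate comparisons of each cluster against the remaining
  population, flagged increased / decreased / neutral at alpha;
* pairwise log-rank tests between cluster survival curves;
* Table-1-style cohort summaries (counts and percentages to one decimal,
  median [Q1, Q3] age) per cluster and overall.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.stats import chi2_contingency

__all__ = [
    "CharlsonMap",
    "load_charlson_map",
    "charlson_index",
    "km_survival",
    "return_rates",
    "medication_rates",
    "relative_risk",
    "rate_comparison",
    "cohort_summary",
    "cluster_outcomes",
    "ClusterOutcomes",
]

_DATA_DIR = Path(__file__).parent / "data"

# Within these pairs the more severe category supersedes the milder one.
_HIERARCHY = {
    "any_malignancy": "metastatic_solid_tumor",
    "mild_liver_disease": "moderate_severe_liver_disease",
    "diabetes_without_complication": "diabetes_with_complication",
}


@dataclass
class CharlsonMap:
    """ICD-10 prefix -> (comorbidity category, weight)."""

    prefixes: dict[str, tuple[str, int]]

    @property
    def max_prefix_len(self) -> int:
        return max(len(p) for p in self.prefixes)


def load_charlson_map(path: str | Path | None = None) -> CharlsonMap:
    path = Path(path) if path is not None else _DATA_DIR / "charlson_icd10.csv"
    df = pd.read_csv(path, dtype={"prefix": str, "category": str, "weight": int})
    weights = df.groupby("category")["weight"].nunique()
    if (weights > 1).any():
        bad = weights[weights > 1].index.tolist()
        raise ValueError(f"categories with conflicting weights: {bad}")
    return CharlsonMap({r.prefix.upper(): (r.category, int(r.weight)) for r in df.itertuples()})


def charlson_index(codes: Iterable[str], cmap: CharlsonMap | None = None) -> int:
    """Charlson comorbidity index for one encounter's diagnosis codes.

    Codes are matched by longest prefix after upper-casing and dot removal;
    each category counts once, severity hierarchies apply (metastatic tumor
    supersedes other malignancy, severe liver disease supersedes mild,
    complicated diabetes supersedes uncomplicated). Unmatched codes score 0.
    """
    if cmap is None:
        cmap = load_charlson_map()
    cats: dict[str, int] = {}
    maxlen = cmap.max_prefix_len
    for code in codes:
        norm = str(code).upper().replace(".", "")
        for ln in range(min(len(norm), maxlen), 0, -1):
            hit = cmap.prefixes.get(norm[:ln])
            if hit is not None:
                cats[hit[0]] = hit[1]
                break
    for mild, severe in _HIERARCHY.items():
        if severe in cats:
            cats.pop(mild, None)
    return sum(cats.values())


def km_survival(
    times: Sequence[float], events: Sequence[int], horizon: int = 365
) -> tuple[pd.DataFrame, float]:
    """Product-limit survival estimate from follow-up times (days) and
    death flags (1 = death, 0 = censored).

    Returns the step curve (time, survival, at_risk) and S(horizon).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no subjects")
    if (times < 0).any():
        raise ValueError("negative follow-up time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    curve = pd.DataFrame(
        {
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
            "at_risk": kmf.event_table["at_risk"].reindex(
                kmf.survival_function_.index
            ).to_numpy(),
        }
    )
    s_h = float(kmf.predict(horizon))
    return curve, s_h


def return_rates(
    records: pd.DataFrame, windows: Sequence[int] = (183, 365)
) -> dict[str, float]:
    """Fraction of encounters with >= 1 return within (0, window] days.

    ``records`` carries per-encounter lists of day offsets in columns
    ``return_days`` (all-cause) and ``opioid_return_days``.
    """
    out = {}
    n = len(records)
    for w in windows:
        for col, label in (("return_days", "all_cause"), ("opioid_return_days", "opioid")):
            if n == 0:
                out[f"{label}_{w}d"] = 0.0
                continue
            hits = records[col].apply(
                lambda days: any(0 < d <= w for d in (days or []))
            )
            out[f"{label}_{w}d"] = float(hits.mean())
    return out


def medication_rates(records: pd.DataFrame) -> dict[str, float]:
    """Per-drug outpatient prescription rates (fraction of encounters)."""
    out = {}
    for drug in ("buprenorphine", "methadone", "naloxone"):
        col = f"{drug}_rx"
        out[drug] = float(records[col].mean()) if len(records) else 0.0
    return out


def relative_risk(a: int, n_c: int, A: int, N: int) -> float:
    """RR of a variable in one cluster vs all remaining encounters.

    RR = (a / n_c) / ((A - a) / (N - n_c)). Returns math.inf when the
    variable is absent outside the cluster but present inside it.
    """
    if n_c <= 0:
        raise ValueError("cluster is empty")
    if N <= n_c:
        raise ValueError("cluster is the whole population")
    if A < a:
        raise ValueError("total count smaller than cluster count")
    rest = (A - a) / (N - n_c)
    if rest == 0:
        return math.inf if a > 0 else math.nan
    return (a / n_c) / rest


def rate_comparison(
    a: int, n1: int, b: int, n2: int, alpha: float = 0.05
) -> tuple[float, float, str]:
    """Pearson chi-square (no continuity correction) of cluster vs rest rates.

    Returns (statistic, p, flag) with flag in {"increased", "decreased",
    "neutral"} relative to the rest. Degenerate tables are neutral.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both groups must be non-empty")
    table = np.array([[a, n1 - a], [b, n2 - b]], dtype=float)
    if table.sum(axis=0).min() == 0:
        warnings.warn("degenerate rate table: all successes or all failures", stacklevel=2)
        return 0.0, 1.0, "neutral"
    stat, p, _dof, _exp = chi2_contingency(table, correction=False)
    flag = "neutral"
    if p < alpha:
        flag = "increased" if a / n1 > b / n2 else "decreased"
    return float(stat), float(p), flag


def _pct(count: int, n: int) -> float:
    return round(100.0 * count / n, 1) if n else 0.0


def cohort_summary(
    encounters: pd.DataFrame,
    labels: Mapping[str, int] | pd.Series,
    categorical: Sequence[str] = ("sex", "insurance", "race", "ethnicity", "esi", "disposition"),
    binary_vars: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-cluster and overall characteristic table.

    One row per (variable, level); columns per cluster plus ``overall``, each
    holding "count (pct)" with the percentage to one decimal of the cluster
    size. Age is summarized as median [Q1, Q3].
    """
    labels = pd.Series(labels)
    if encounters["encounter_id"].isin(labels.index).all():
        lab = encounters["encounter_id"].map(labels)
    else:
        raise ValueError("every encounter must carry a cluster label")
    if lab.isna().any():
        raise ValueError("every encounter must carry a cluster label")
    df = encounters.assign(_cluster=lab.to_numpy())
    groups: list[tuple[str, pd.DataFrame]] = [("overall", df)] + [
        (str(c), g) for c, g in df.groupby("_cluster")
    ]
    rows = []
    n_row = {"variable": "n", "level": ""}
    age_row = {"variable": "age", "level": "median [Q1,Q3]"}
    for name, g in groups:
        n_row[name] = str(len(g))
        q1, med, q3 = g["age"].quantile([0.25, 0.5, 0.75])
        age_row[name] = f"{med:.1f} [{q1:.1f},{q3:.1f}]"
    rows.extend([n_row, age_row])
    for var in categorical:
        for level in sorted(df[var].astype(str).unique()):
            row = {"variable": var, "level": level}
            for name, g in groups:
                cnt = int((g[var].astype(str) == level).sum())
                row[name] = f"{cnt} ({_pct(cnt, len(g))})"
            rows.append(row)
    for var in binary_vars:
        row = {"variable": var, "level": "yes"}
        for name, g in groups:
            cnt = int(g[var].astype(bool).sum())
            row[name] = f"{cnt} ({_pct(cnt, len(g))})"
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ClusterOutcomes:
    """Per-cluster outcome report plus cross-cluster comparisons."""

    per_cluster: pd.DataFrame
    km_curves: dict[int, pd.DataFrame]
    logrank_p: pd.DataFrame  # pairwise matrix
    rate_flags: pd.DataFrame  # (cluster, rate) -> flag
    alpha: float = 0.05

    def to_json_dict(self) -> dict:
        return {
            "per_cluster": self.per_cluster.to_dict(orient="index"),
            "logrank_p": self.logrank_p.to_dict(),
            "rate_flags": self.rate_flags.to_dict(orient="index"),
            "alpha": self.alpha,
        }


_RATE_COLS = [
    "all_cause_183d", "all_cause_365d", "opioid_183d", "opioid_365d",
    "buprenorphine", "methadone", "naloxone",
]


def cluster_outcomes(
    records: pd.DataFrame,
    labels: Mapping[str, int] | pd.Series,
    cmap: CharlsonMap | None = None,
    horizon: int = 365,
    alpha: float = 0.05,
) -> ClusterOutcomes:
    """Assemble the full per-cluster outcome profile.

    ``records`` needs columns: encounter_id, followup_days, death (0/1),
    return_days, opioid_return_days, buprenorphine_rx, methadone_rx,
    naloxone_rx, diagnosis_codes (list of ICD-10 strings).
    """
    if cmap is None:
        cmap = load_charlson_map()
    labels = pd.Series(labels)
    lab = records["encounter_id"].map(labels)
    if lab.isna().any():
        raise ValueError("every encounter needs an outcome record and a cluster label")
    df = records.assign(_cluster=lab.to_numpy())
    clusters = sorted(df["_cluster"].unique())
    rows = {}
    curves = {}
    flag_rows = {}
    for c in clusters:
        g = df[df["_cluster"] == c]
        rest = df[df["_cluster"] != c]
        if len(g) < 2:
            warnings.warn(f"cluster {c} has fewer than 2 subjects", stacklevel=2)
        curve, s_h = km_survival(g["followup_days"], g["death"], horizon)
        curves[int(c)] = curve
        cci = g["diagnosis_codes"].apply(lambda codes: charlson_index(codes or [], cmap))
        row = {
            "n": len(g),
            f"survival_{horizon}d": s_h,
            "cci_mean": float(cci.mean()),
            "cci_median": float(cci.median()),
        }
        row.update(return_rates(g))
        row.update(medication_rates(g))
        flags = {}
        if len(rest):
            rest_rates = {**return_rates(rest), **medication_rates(rest)}
            for rc in _RATE_COLS:
                a = int(round(row[rc] * len(g)))
                b = int(round(rest_rates[rc] * len(rest)))
                _stat, p, flag = rate_comparison(a, len(g), b, len(rest), alpha)
                flags[rc] = flag
        else:
            flags = {rc: "neutral" for rc in _RATE_COLS}
        rows[int(c)] = row
        flag_rows[int(c)] = flags
    logrank = pd.DataFrame(np.nan, index=clusters, columns=clusters)
    for i, ci in enumerate(clusters):
        for cj in clusters[i + 1:]:
            gi = df[df["_cluster"] == ci]
            gj = df[df["_cluster"] == cj]
            res = logrank_test(
                gi["followup_days"], gj["followup_days"],
                event_observed_A=gi["death"], event_observed_B=gj["death"],
            )
            logrank.loc[ci, cj] = logrank.loc[cj, ci] = res.p_value
    return ClusterOutcomes(
        per_cluster=pd.DataFrame(rows).T,
        km_curves=curves,
        logrank_p=logrank,
        rate_flags=pd.DataFrame(flag_rows).T,
        alpha=alpha,
    )
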