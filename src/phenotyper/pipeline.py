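"""End-to-end orchestration: simulate -> extract -> corpus -> topics ->
embed -> cluster -> outcomes.

Stages communicate only through files under the run directory, so any stage's
input can be replaced by output from an external tool (a full NLP annotator,
a different topic modeler) in the same format. Every run writes a manifest
recording parameters, seeds and SHA-256 checksums of each artifact; rerunning
with the same config and seed reproduces the manifest checksums exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, corpus_builder, outcomes, synthetic_ehr, topic_model
from .concept_extraction import (
    default_lexicon_path, extract_concepts, filter_by_semantic_type,
    load_allowlist, load_lexicon,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("phenotyper")


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    simulate: dict | None = None          # SimulationConfig overrides; None -> load dataset_dir
    dataset_dir: str | None = None
    corpus: dict = field(default_factory=dict)    # freq_threshold, alpha
    topics: dict = field(default_factory=dict)    # k | k_grid, n_iterations, burn_in, plateau_epsilon
    cluster: dict = field(default_factory=dict)   # k | k_grid, n_init
    outcomes: dict = field(default_factory=dict)  # alpha, horizon

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _note_tokens(dataset: synthetic_ehr.SyntheticDataset, lexicon, allowlist) -> dict[str, list[list[str]]]:
    """Per-encounter note token lists, extracting concepts when notes carry
    rendered text rather than pre-tokenized output."""
    per_enc: dict[str, list[list[str]]] = {}
    for idx, rec in enumerate(dataset.notes):
        if "tokens" in rec and not rec.get("text"):
            toks = list(rec["tokens"])
        else:
            mentions = extract_concepts(rec["text"], lexicon, rec["encounter_id"], idx)
            mentions = filter_by_semantic_type(mentions, allowlist)
            toks = [m.surface for m in mentions]
        per_enc.setdefault(rec["encounter_id"], []).append(toks)
    return per_enc


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def record(stage: str, params: dict, paths: list[Path]) -> None:
        manifest["stages"][stage] = {
            "params": params,
            "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in paths},
        }
        log.info("stage %s done: %d artifacts", stage, len(paths))

    # 1. simulate (or load)
    try:
        if config.simulate is not None:
            sim_cfg = synthetic_ehr.default_config(seed=config.seed, **config.simulate)
            dataset = synthetic_ehr.generate_dataset(sim_cfg)
            data_dir = outdir / "dataset"
            synthetic_ehr.write_dataset(dataset, data_dir)
            record("simulate", dataclasses.asdict(sim_cfg),
                   sorted(data_dir.iterdir()))
        elif config.dataset_dir:
            dataset = synthetic_ehr.read_dataset(config.dataset_dir)
            record("simulate", {"loaded_from": str(config.dataset_dir)}, [])
        else:
            raise ValueError("config needs either a simulate block or dataset_dir")
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    # 2. concept extraction / tokenization
    try:
        lexicon = load_lexicon(default_lexicon_path())
        allowlist = load_allowlist()
        note_tokens = _note_tokens(dataset, lexicon, allowlist)
    except Exception as exc:
        raise RuntimeError(f"stage 'extract' failed: {exc}") from exc

    # 3. corpus: bags, lab reference, frequency + chi-square filters
    try:
        freq_threshold = config.corpus.get("freq_threshold", 0.05)
        alpha = config.corpus.get("alpha", 0.05)
        is_opioid = dict(zip(dataset.encounters["encounter_id"],
                             dataset.encounters["cohort"] == "opioid"))
        bg_labs = dataset.labs[
            ~dataset.labs["encounter_id"].map(is_opioid).astype(bool)
        ]
        lab_ref = (corpus_builder.compute_lab_reference(bg_labs)
                   if not bg_labs.empty else corpus_builder.LabReference({}))
        dx_groups = dataset.diagnoses.groupby("encounter_id")["group"].apply(list)
        meds = dataset.medications.groupby("encounter_id")["drug"].apply(list)
        labs_by_enc: dict[str, list] = {}
        for row in dataset.labs.itertuples():
            labs_by_enc.setdefault(row.encounter_id, []).append((row.lab_name, row.value))
        op_bags, bg_bags = [], []
        for eid in dataset.encounters["encounter_id"]:
            structured = corpus_builder.structured_tokens(
                dx_groups.get(eid, []), meds.get(eid, []),
                labs_by_enc.get(eid, []), lab_ref,
            )
            bag = corpus_builder.combine_encounter_tokens(
                note_tokens.get(eid, []), structured, encounter_id=eid,
                cohort="opioid" if is_opioid[eid] else "background",
            )
            (op_bags if is_opioid[eid] else bg_bags).append(bag)
        removed = corpus_builder.frequency_filter(op_bags, bg_bags, freq_threshold)
        decisions = corpus_builder.chisq_keep_words(op_bags, bg_bags, removed, alpha)
        keep = [d.token for d in decisions if d.keep]
        corpus = corpus_builder.build_corpus(op_bags, keep)
        corpus_dir = outdir / "corpus"
        corpus.save(corpus_dir)
        corpus_builder.decisions_to_frame(decisions).to_csv(
            corpus_dir / "decisions.csv", index=False
        )
        (corpus_dir / "params.json").write_text(
            json.dumps({"freq_threshold": freq_threshold, "alpha": alpha,
                        "n_removed": len(removed), "n_keep": len(keep)})
        )
        record("corpus", {"freq_threshold": freq_threshold, "alpha": alpha},
               sorted(corpus_dir.iterdir()))
    except Exception as exc:
        raise RuntimeError(f"stage 'corpus' failed: {exc}") from exc

    # 4. topics
    try:
        tp = dict(config.topics)
        k_grid = tp.pop("k_grid", None)
        k = tp.pop("k", None)
        plateau_epsilon = tp.pop("plateau_epsilon", 0.05)
        model_dir = outdir / "model"
        if k is None:
            profile = topic_model.select_topic_count(
                corpus, k_grid or [5, 10, 20], plateau_epsilon=plateau_epsilon,
                seed=config.seed, **tp,
            )
            k = profile.chosen_k
            model_dir.mkdir(parents=True, exist_ok=True)
            profile.to_frame().to_csv(model_dir / "coherence.csv", index=False)
        model = topic_model.fit_lda(corpus, k, seed=config.seed, **tp)
        model.save(model_dir)
        topwords = {
            t: [w for w, _ in topic_model.top_words(model, t, 30)] for t in range(model.K)
        }
        (model_dir / "top_words.json").write_text(json.dumps(topwords))
        record("topics", {"K": k, **tp}, sorted(model_dir.iterdir()))
    except Exception as exc:
        raise RuntimeError(f"stage 'topics' failed: {exc}") from exc

    # 5. embeddings
    try:
        embeddings = topic_model.embed_encounters(model, corpus)
        emb_path = outdir / "embeddings.csv"
        embeddings.to_csv(emb_path)
        record("embed", {"K": model.K}, [emb_path])
    except Exception as exc:
        raise RuntimeError(f"stage 'embed' failed: {exc}") from exc

    # 6. clustering
    try:
        cp = dict(config.cluster)
        k_grid = cp.pop("k_grid", None)
        kc = cp.pop("k", None)
        cluster_dir = outdir / "clusters"
        cluster_dir.mkdir(parents=True, exist_ok=True)
        if kc is None:
            kc, metrics = clustering.select_k(
                embeddings, k_grid or list(range(2, 9)), seed=config.seed, **cp
            )
            metrics.to_csv(cluster_dir / "metrics.csv", index=False)
        fit = clustering.kmeans_fit(embeddings, kc, seed=config.seed, **cp)
        fit.to_frame(corpus.encounter_ids).to_csv(cluster_dir / "assignments.csv")
        record("cluster", {"k": kc, "mean_silhouette": fit.mean_silhouette,
                           "dunn": fit.dunn}, sorted(cluster_dir.iterdir()))
        labels = pd.Series(fit.labels, index=corpus.encounter_ids)
    except Exception as exc:
        raise RuntimeError(f"stage 'cluster' failed: {exc}") from exc

    # 7. outcomes
    try:
        report_dir = outdir / "report"
        report_dir.mkdir(parents=True, exist_ok=True)
        records = synthetic_ehr.outcome_records(dataset)
        oc_alpha = config.outcomes.get("alpha", 0.05)
        horizon = config.outcomes.get("horizon", 365)
        report = outcomes.cluster_outcomes(records, labels, horizon=horizon, alpha=oc_alpha)
        (report_dir / "cluster_outcomes.json").write_text(
            json.dumps(report.to_json_dict(), default=str)
        )
        report.per_cluster.to_csv(report_dir / "per_cluster.csv")
        for c, curve in report.km_curves.items():
            curve.to_csv(report_dir / f"km_cluster_{c}.csv", index=False)
        # Table-1-style summary with diagnosis-group prevalences as binary variables
        enc_op = dataset.encounters[dataset.encounters["cohort"] == "opioid"].copy()
        groups = sorted(dataset.diagnoses["group"].unique()) if len(dataset.diagnoses) else []
        have = dataset.diagnoses.groupby("group")["encounter_id"].apply(set).to_dict()
        for grp in groups:
            enc_op[grp] = enc_op["encounter_id"].isin(have.get(grp, set()))
        summary = outcomes.cohort_summary(enc_op, labels, binary_vars=groups)
        summary.to_csv(report_dir / "summary.csv", index=False)
        # RR matrix (clusters x diagnosis groups), heatmap-ready
        rr_rows = {}
        N = len(enc_op)
        for c in sorted(labels.unique()):
            members = set(labels.index[labels == c])
            n_c = len(members)
            rr_rows[c] = {}
            for grp in groups:
                a = len(have.get(grp, set()) & members)
                A = len(have.get(grp, set()) & set(enc_op["encounter_id"]))
                rr_rows[c][grp] = (outcomes.relative_risk(a, n_c, A, N)
                                   if 0 < n_c < N else float("nan"))
        pd.DataFrame(rr_rows).T.to_csv(report_dir / "rr_matrix.csv")
        record("outcomes", {"alpha": oc_alpha, "horizon": horizon},
               sorted(report_dir.iterdir()))
    except Exception as exc:
        raise RuntimeError(f"stage 'outcomes' failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
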