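"""End-to-end orchestration of the two experiments.

``run_discovery_experiment`` chains the full classifier pipeline on one
configuration: derive labels -> quantile-normalize -> resampled hill-climb
signature discovery -> final SVM (frozen with a reference distribution and a
zero-false-positive operating threshold) -> stratified cross-validation ->
full-range evaluation -> frozen-model application to batch-shifted
validation cohorts.

``run_prognosis_experiment`` computes classifier scores on a survival
cohort, their Spearman correlation with tumour regression, and top/bottom
50% Kaplan-Meier curves with log-rank tests for each endpoint.

Both are pure functions of (inputs, RunConfig, master seed); artifacts are
plain JSON/TSV without timestamps so reruns are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics, preprocess, ratio_score, signature_discovery, svm_classifier
from .core_data import CohortBundle
from .simdata import SimulationConfig, generate_cohort, generate_validation_cohort

logger = logging.getLogger("pcrsig")

__all__ = ["RunConfig", "run_discovery_experiment", "run_prognosis_experiment"]


@dataclass
class RunConfig:
    """Parameters of one orchestrated run; serialized next to the outputs."""

    seed: int = 0
    out_dir: str = "pcrsig_run"
    # discovery
    n_repetitions: int = 100
    alpha: float = 0.05
    pool_size: int = 100
    train_fraction: float = 0.75
    svm_cost: float = 1.0
    cv_folds: int = 4
    # synthetic inputs (used when no explicit bundles are supplied)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    n_intermediate_full: int = 97
    validation_batch_shifts: tuple[float, ...] = (3.0,)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "sim"}
        d["validation_batch_shifts"] = list(self.validation_batch_shifts)
        d["sim"] = self.sim.to_dict()
        return d


def _write_json(path: Path, payload: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def _default_cohorts(config: RunConfig) -> tuple[CohortBundle, CohortBundle, list[CohortBundle]]:
    """Discovery extremes, full-range cohort, and validation cohorts."""
    import dataclasses

    sim = config.sim
    full_cfg = dataclasses.replace(
        sim, n_intermediate=config.n_intermediate_full, seed=sim.seed
    )
    full = generate_cohort(full_cfg, cohort_label="full_range")
    discovery = full.restrict_to_extremes()
    validations = []
    for i, shift in enumerate(config.validation_batch_shifts):
        vcfg = dataclasses.replace(
            sim,
            n_positive=max(4, sim.n_positive // 4),
            n_negative=max(4, sim.n_negative // 4),
            n_intermediate=0,
            batch_shift=shift,
            seed=sim.seed + 1000 + i,
        )
        validations.append(generate_validation_cohort(vcfg, full, f"validation_{i}"))
    return discovery, full, validations


def run_discovery_experiment(
    config: RunConfig,
    discovery: CohortBundle | None = None,
    full_cohort: CohortBundle | None = None,
    validation_cohorts: list[CohortBundle] | None = None,
) -> dict:
    """Run discovery -> final SVM -> CV -> full-range and frozen validation.

    Returns the artifact payloads and writes them under ``config.out_dir``:
    ``signature.json``, ``model.json``, ``evaluation.json``, ``config.json``.
    """
    out = Path(config.out_dir)
    if discovery is None:
        discovery, full_cohort, validation_cohorts = _default_cohorts(config)
    if full_cohort is None:
        full_cohort = discovery
    validation_cohorts = validation_cohorts or []

    logger.info("stage=normalize seed=%d", config.seed)
    full_norm = full_cohort.__class__(
        expression=preprocess.quantile_normalize(full_cohort.expression),
        annotation=full_cohort.annotation,
        labels=full_cohort.labels,
    )
    reference = preprocess.reference_quantiles(full_norm.expression)
    disc_norm = full_norm.subset_samples(discovery.sample_ids)

    logger.info("stage=discover reps=%d pool=%d", config.n_repetitions, config.pool_size)
    sig_result = signature_discovery.discover_signature(
        disc_norm,
        n_repetitions=config.n_repetitions,
        alpha=config.alpha,
        pool_size=config.pool_size,
        train_fraction=config.train_fraction,
        C=config.svm_cost,
        seed=config.seed,
    )
    signature = sig_result.signature
    if not signature:
        raise RuntimeError("discovery produced an empty signature")

    logger.info("stage=train signature_size=%d", len(signature))
    model = svm_classifier.train_svm(
        disc_norm, signature, C=config.svm_cost, reference=reference, seed=config.seed
    )
    cv_report = svm_classifier.cross_validate(
        disc_norm, signature, k=config.cv_folds, C=config.svm_cost, seed=config.seed
    )

    # full-range evaluation: positives are pCR, everything else counts negative
    full_scores = svm_classifier.svm_decision_values(model, full_norm.expression)
    y_full = full_norm.positive_mask()
    full_report = metrics.evaluate_scores(full_scores, y_full)

    validation_reports = []
    for v in validation_cohorts:
        aligned = preprocess.align_to_reference(v.expression, reference)
        decisions = svm_classifier.svm_decision_values(model, aligned)
        calls = decisions > model.operating_threshold
        y = v.positive_mask()
        rep = metrics.evaluate_scores(decisions, y)
        validation_reports.append({
            "cohort": v.annotation[0].cohort_label if v.annotation else "",
            "auc": rep.auc,
            "sens_at_zero_fpr": rep.sens_at_zero_fpr,
            "threshold_sensitivity": float(calls[y].mean()),
            "threshold_false_positives": int(calls[~y].sum()),
            "n_positive": rep.n_positive,
            "n_negative": rep.n_negative,
        })

    payload = {
        "signature": sig_result.to_dict(),
        "model": model.to_dict(),
        "evaluation": {
            "cross_validation": {
                "auc": cv_report.auc, "sens_at_zero_fpr": cv_report.sens_at_zero_fpr,
            },
            "full_range": {
                "auc": full_report.auc, "sens_at_zero_fpr": full_report.sens_at_zero_fpr,
                "n_positive": full_report.n_positive, "n_negative": full_report.n_negative,
            },
            "validation": validation_reports,
        },
    }
    _write_json(out / "signature.json", payload["signature"])
    _write_json(out / "model.json", payload["model"])
    _write_json(out / "evaluation.json", payload["evaluation"])
    _write_json(out / "config.json", config.to_dict())
    return payload


def run_prognosis_experiment(
    config: RunConfig,
    cohort: CohortBundle,
    scores: np.ndarray | None = None,
    score_definition: ratio_score.RatioScore | None = None,
    unlog: bool = True,
) -> dict:
    """Score-based prognosis: Spearman vs TRG, median split, KM + log-rank.

    ``scores`` may be supplied directly (e.g. SVM decision values); otherwise
    they are computed from ``score_definition`` (default: the published
    ratio score cannot apply to synthetic gene names, so a definition must
    be given when scores are not).
    """
    out = Path(config.out_dir)
    if scores is None:
        if score_definition is None:
            raise ValueError("provide scores or a score_definition")
        scores = ratio_score.compute_ratio_score(
            cohort.expression, score_definition, unlog=unlog
        )
    scores = np.asarray(scores, dtype=float)

    trg = np.array([a.trg_percent for a in cohort.annotation], dtype=float)
    order = {s: i for i, s in enumerate(cohort.sample_ids)}
    trg = trg[[order[a.sample_id] for a in cohort.annotation]]  # aligned
    rho, rho_p = metrics.spearman_rho(scores, trg)

    groups = metrics.median_split(scores)
    results: dict = {"spearman_rho": rho, "spearman_p": rho_p, "endpoints": {}}
    ann = {a.sample_id: a for a in cohort.annotation}
    for endpoint in ("os", "dfs"):
        times, events = [], []
        for s in cohort.sample_ids:
            a = ann[s]
            t = getattr(a, f"{endpoint}_time")
            e = getattr(a, f"{endpoint}_event")
            if t is None or e is None:
                times = []
                break
            times.append(t)
            events.append(e)
        if not times:
            continue
        comp = metrics.logrank_test(groups, np.asarray(times), np.asarray(events))
        results["endpoints"][endpoint] = {
            "chi_square": comp.chi_square,
            "p_value": comp.p_value,
            "n_high": int((groups == "high").sum()),
            "n_low": int((groups == "low").sum()),
        }
    if not results["endpoints"]:
        raise ValueError("no usable survival endpoint (missing times/events)")

    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "sample_id": cohort.sample_ids,
        "score": scores,
        "group": groups,
        "trg_percent": trg,
    }).to_csv(out / "scores.tsv", sep="\t", index=False)
    _write_json(out / "km.json", results)
    return results
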