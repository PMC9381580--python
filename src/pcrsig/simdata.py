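"""Synthetic expression cohorts with planted treatment-response structure.

The generator emulates the statistical design of a pretreatment rectal-cancer
expression study on the log2 scale: per-gene baseline means drawn uniformly
from [6, 14] (a typical microarray dynamic range, and safely positive so that
linear-scale ratio scores are well defined), Gaussian within-class noise, and
a subset of *informative* genes whose mean is shifted upward in pathological
complete responders (TRG = 100%). Tumour regression grades are assigned
100% to positives, uniform over [10, 44.9] to poor responders and
[45, 99.9] to intermediates, matching an extreme-response discovery design
of 32 + 32 cases inside a 161-case full-range cohort.

Three cohort flavours:

* :func:`generate_cohort` — discovery or full-range cohort;
* :func:`generate_validation_cohort` — same gene universe as a reference
  cohort plus an additive batch shift (what reference-anchored quantile
  alignment is meant to remove);
* :func:`generate_survival_cohort` — follow-up cohort whose hazard is tied
  to a latent signature score, for exercising score-based prognosis.

All randomness flows from one seed through independent named substreams, so
a bundle is a pure function of its configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .core_data import (
    CohortBundle,
    ExpressionMatrix,
    SampleAnnotation,
    derive_labels,
)

__all__ = [
    "SimulationConfig",
    "generate_cohort",
    "generate_validation_cohort",
    "generate_survival_cohort",
    "latent_signature_score",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    ``effect_size`` is the mean log2 shift of the first ``n_informative``
    genes in positive (pCR) samples relative to negatives; ``noise_sd`` the
    per-gene within-class standard deviation (log2 units). With
    ``graded_effect`` the informative shift scales linearly with TRG instead
    of being a pure class effect, so score-vs-TRG correlation analyses have
    signal across the full regression range.
    """

    n_genes: int = 500
    n_informative: int = 10
    n_positive: int = 32
    n_negative: int = 32
    n_intermediate: int = 0
    effect_size: float = 2.0
    noise_sd: float = 1.0
    batch_shift: float = 0.0
    graded_effect: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative must be <= n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _gene_means(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(6.0, 14.0, size=config.n_genes)


def _trg_values(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    trg = np.concatenate([
        np.full(config.n_positive, 100.0),
        rng.uniform(10.0, 44.9, size=config.n_negative),
        rng.uniform(45.0, 99.9, size=config.n_intermediate),
    ])
    return trg


def _effect_matrix(config: SimulationConfig, trg: np.ndarray) -> np.ndarray:
    """Per-(gene, sample) mean shift of the informative genes."""
    n_samples = len(trg)
    shift = np.zeros((config.n_genes, n_samples))
    if config.graded_effect:
        # shift grows linearly from 0 at TRG=10 to effect_size at TRG=100
        scale = np.clip((trg - 10.0) / 90.0, 0.0, 1.0)
    else:
        scale = (trg == 100.0).astype(float)
    shift[: config.n_informative, :] = config.effect_size * scale
    return shift


def _assemble(
    config: SimulationConfig,
    values: np.ndarray,
    trg: np.ndarray,
    cohort_label: str,
    sample_prefix: str = "S",
) -> CohortBundle:
    n_samples = values.shape[1]
    probe_ids = [f"P{i:05d}" for i in range(config.n_genes)]
    gene_symbols = [f"G{i:05d}" for i in range(config.n_genes)]
    sample_ids = [f"{sample_prefix}{j:04d}" for j in range(n_samples)]
    expr = ExpressionMatrix(values, probe_ids, gene_symbols, sample_ids)
    annotation = [
        SampleAnnotation(sample_id=s, trg_percent=float(t), cohort_label=cohort_label)
        for s, t in zip(sample_ids, trg)
    ]
    labels = derive_labels(annotation)
    return CohortBundle(expression=expr, annotation=annotation, labels=labels)


def generate_cohort(config: SimulationConfig, cohort_label: str = "sim") -> CohortBundle:
    """Generate a cohort under ``config``; bit-identical under the same seed."""
    rng_means, rng_trg, rng_noise = _streams(config.seed, 3)
    means = _gene_means(config, rng_means)
    trg = _trg_values(config, rng_trg)
    n_samples = len(trg)
    noise = rng_noise.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    values = means[:, None] + _effect_matrix(config, trg) + noise + config.batch_shift
    return _assemble(config, values, trg, cohort_label)


def generate_validation_cohort(
    config: SimulationConfig,
    reference_bundle: CohortBundle,
    cohort_label: str = "validation",
) -> CohortBundle:
    """Generate a batch-shifted cohort on the gene universe of a reference.

    Per-gene baselines are estimated from the reference cohort's poor
    responders (whose informative genes are unshifted under the class-effect
    model), so the validation cohort measures the same platform baseline in
    a different batch; the usual class-effect and noise model then applies,
    plus ``config.batch_shift`` added to every value.
    """
    ref_expr = reference_bundle.expression
    if ref_expr.n_probes != config.n_genes:
        raise ValueError(
            f"gene universe mismatch: reference has {ref_expr.n_probes} genes, "
            f"config expects {config.n_genes}"
        )
    _, rng_trg, rng_noise = _streams(config.seed, 3)
    baseline_mask = reference_bundle.label_array() == "negative"
    if not baseline_mask.any():
        baseline_mask = np.ones(ref_expr.n_samples, dtype=bool)
    means = ref_expr.values[:, baseline_mask].mean(axis=1)
    trg = _trg_values(config, rng_trg)
    n_samples = len(trg)
    noise = rng_noise.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
    values = means[:, None] + _effect_matrix(config, trg) + noise + config.batch_shift
    bundle = _assemble(config, values, trg, cohort_label, sample_prefix="V")
    # keep the reference's probe/gene identifiers (same platform)
    bundle.expression.probe_ids = list(ref_expr.probe_ids)
    bundle.expression.gene_symbols = list(ref_expr.gene_symbols)
    return bundle


def latent_signature_score(
    bundle: CohortBundle, n_informative: int, noise_sd: float = 1.0
) -> np.ndarray:
    """Standardized mean of the informative-gene residuals per sample.

    This is the latent score the survival generator links to hazard; it is
    recomputable from a generated bundle because informative genes are by
    convention the first ``n_informative`` rows.
    """
    v = bundle.expression.values[:n_informative, :]
    centered = v - v.mean(axis=1, keepdims=True)
    return centered.mean(axis=0) / (noise_sd / np.sqrt(n_informative))


def generate_survival_cohort(
    n: int,
    score_link_coefficient: float,
    censor_rate: float,
    seed: int,
    n_genes: int = 50,
    n_informative: int = 10,
    noise_sd: float = 1.0,
    baseline_hazard: float = 0.1,
) -> CohortBundle:
    """Cohort with overall- and disease-free-survival follow-up.

    Event times are exponential with per-sample hazard
    ``baseline_hazard * exp(-score_link_coefficient * z)`` where ``z`` is the
    latent signature score, so a positive coefficient makes high-score
    patients live longer. A fraction ``censor_rate`` of samples (in
    expectation) is censored uniformly before its event time.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    config = SimulationConfig(
        n_genes=n_genes,
        n_informative=n_informative,
        n_positive=0,
        n_negative=0,
        n_intermediate=n,
        effect_size=0.0,
        noise_sd=noise_sd,
        seed=seed,
    )
    rng_means, rng_trg, rng_noise, rng_surv = _streams(seed, 4)
    means = _gene_means(config, rng_means)
    trg = rng_trg.uniform(10.0, 100.0, size=n)
    noise = rng_noise.normal(0.0, noise_sd, size=(n_genes, n))
    values = means[:, None] + noise
    bundle = _assemble(config, values, trg, "survival", sample_prefix="T")

    z = latent_signature_score(bundle, n_informative, noise_sd)
    hazard = baseline_hazard * np.exp(-score_link_coefficient * z)
    for endpoint in ("os", "dfs"):
        event_time = rng_surv.exponential(1.0 / hazard)
        censored = rng_surv.uniform(size=n) < censor_rate
        obs_time = np.where(
            censored, rng_surv.uniform(0.0, 1.0, size=n) * event_time, event_time
        )
        event = (~censored).astype(int)
        for a, t_obs, ev in zip(bundle.annotation, obs_time, event):
            setattr(a, f"{endpoint}_time", float(t_obs))
            setattr(a, f"{endpoint}_event", int(ev))
    return bundle
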