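"""The normalization-free ratio-of-sums score classifier.

An SVM needs its inputs on the training distribution, hence normalization.
The ratio score avoids that: it is the sum of expression of a numerator gene
set divided by the sum of a denominator gene set,

    score(sample) = sum_{g in numerator} Exp_g / sum_{g in denominator} Exp_g,

computed on positive linear-scale intensities "as is". Multiplying every
value by a constant cancels, so the score is invariant to global scaling and
can be applied to un-normalized data, including single samples.

:func:`published_score` returns the frozen 21-gene instance exactly as
printed in the original report (14 numerator / 12 denominator symbols, seven
genes shared, legacy nomenclature preserved and resolved through the alias
table at compute time). :func:`train_score_classifier` learns such a score
from data: a stratified 50/50 split, then 100 random-restart greedy local
searches over per-gene numerator/denominator membership toggles maximizing
training sensitivity at zero false-positive rate, keeping the restart with
the best test-half sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .core_data import CohortBundle, ExpressionMatrix, subset_to_signature
from .metrics import sensitivity_at_zero_fpr
from .signature_discovery import resample_split

__all__ = [
    "RatioScore",
    "published_score",
    "compute_ratio_score",
    "local_search_score",
    "train_score_classifier",
]

#: The published 21-transcript signature: gene symbol -> array probe id.
PUBLISHED_TRANSCRIPT_PROBES: dict[str, str] = {
    "CGREF1": "A_33_P3281850",
    "FZD10": "A_23_P203972",
    "ASPM": "A_23_P52017",
    "SHTN1": "A_23_P202587",
    "CCNB1": "A_23_P122197",
    "CXCL10": "A_24_P303091",
    "CFAP61": "A_32_P4262",
    "XPO1": "A_23_P40078",
    "BRCA1": "A_23_P207400",
    "TMPO": "A_23_P325040",
    "CASC5": "A_23_P100127",
    "FANCM": "A_32_P106732",
    "BLM": "A_23_P88630",
    "HOMER1": "A_33_P3372257",
    "TNPO3": "A_33_P3370132",
    "CENPL": "A_23_P126120",
    "CSPP1": "A_23_P71537",
    "STARD3": "A_33_P3246804",
    "DNAAF3": "A_33_P3286349",
    "MCM5": "A_23_P132277",
    "TSNAX": "A_24_P148151",
}

_PUBLISHED_NUMERATOR = [
    "KIAA1598", "ASPM", "TMPO", "HOMER1", "CXCL10", "CENPL", "BRCA1",
    "FZD10", "C19orf51", "C20orf26", "CASC5", "CCNB1", "FANCM", "BLM",
]
_PUBLISHED_DENOMINATOR = [
    "CGREF1", "TNPO3", "XPO1", "TSNAX", "CENPL", "FANCM", "FZD10",
    "C19orf51", "C20orf26", "CCNB1", "CSPP1", "BLM",
]


@dataclass
class RatioScore:
    """Numerator/denominator gene multisets; overlap is allowed."""

    numerator_genes: list[str]
    denominator_genes: list[str]

    def __post_init__(self) -> None:
        if not self.denominator_genes:
            raise ValueError("denominator gene set must be non-empty")

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in list(self.numerator_genes) + list(self.denominator_genes):
            seen.setdefault(g)
        return list(seen)

    def to_dict(self) -> dict:
        return {
            "numerator": list(self.numerator_genes),
            "denominator": list(self.denominator_genes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RatioScore":
        return cls(list(d["numerator"]), list(d["denominator"]))


def published_score() -> RatioScore:
    """The frozen published 21-gene score (14 numerator / 12 denominator)."""
    return RatioScore(list(_PUBLISHED_NUMERATOR), list(_PUBLISHED_DENOMINATOR))


def compute_ratio_score(
    matrix: ExpressionMatrix,
    score: RatioScore,
    missing: Literal["fail", "drop"] = "fail",
    unlog: bool = False,
) -> np.ndarray:
    """Per-sample ratio of summed expression; no normalization applied.

    ``unlog=True`` exponentiates (2**x) first, for matrices stored on the
    log2 scale — ratio semantics need linear, positive intensities. Missing
    genes either abort (``fail``) or are dropped from their sum with a
    warning (``drop``), which is how partially measured panels are handled.
    """
    def _sum(genes: Sequence[str]) -> np.ndarray:
        sub = subset_to_signature(matrix, list(dict.fromkeys(genes)), missing=missing)
        if sub.n_probes == 0:
            raise ValueError("no genes of the set are present in the matrix")
        v = sub.values
        if unlog:
            v = np.exp2(v)
        if np.any(v <= 0):
            r, c = np.argwhere(v <= 0)[0]
            raise ValueError(
                f"non-positive expression for {sub.gene_symbols[r]!r} in sample "
                f"{sub.sample_ids[c]!r}; ratio scores need positive intensities"
            )
        # honour multiset multiplicity
        mult = np.array([list(genes).count(g) for g in sub.gene_symbols], dtype=float)
        return (v * mult[:, None]).sum(axis=0)

    num = _sum(score.numerator_genes) if score.numerator_genes else 0.0
    den = _sum(score.denominator_genes)
    return num / den


def _vectorized_sens(score_matrix: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Sensitivity at zero FPR for each row of a (moves x samples) matrix."""
    max_neg = score_matrix[:, ~pos].max(axis=1, keepdims=True)
    return (score_matrix[:, pos] > max_neg).sum(axis=1) / pos.sum()


def _search_from(
    V: np.ndarray, pos: np.ndarray, num_mask: np.ndarray, den_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Greedy best-improvement toggling until a local maximum.

    ``V`` is linear-scale expression, genes x samples. Each move toggles one
    gene's membership in one of the two sets; a move emptying the
    denominator is inadmissible. The objective strictly increases at every
    accepted move, so the walk takes at most n_positives steps.
    """
    G = V.shape[0]
    num_s = num_mask @ V
    den_s = den_mask @ V
    current = float(
        sensitivity_at_zero_fpr(num_s / den_s, pos)
    )
    while True:
        sign_num = np.where(num_mask, -1.0, 1.0)[:, None]
        sign_den = np.where(den_mask, -1.0, 1.0)[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            cand_num = (num_s[None, :] + sign_num * V) / den_s[None, :]
            cand_den = num_s[None, :] / (den_s[None, :] + sign_den * V)
        cand = np.vstack([cand_num, cand_den])  # 2G x samples
        admissible = np.ones(2 * G, dtype=bool)
        if den_mask.sum() == 1:
            admissible[G + np.flatnonzero(den_mask)] = False
        obj = np.full(2 * G, -np.inf)
        obj[admissible] = _vectorized_sens(cand[admissible], pos)
        best = int(np.argmax(obj))
        if obj[best] <= current:
            return num_mask, den_mask, current
        current = float(obj[best])
        if best < G:
            num_mask = num_mask.copy()
            num_mask[best] = ~num_mask[best]
        else:
            den_mask = den_mask.copy()
            den_mask[best - G] = ~den_mask[best - G]
        num_s = num_mask @ V
        den_s = den_mask @ V


def _linear_values(
    bundle: CohortBundle, gene_universe: Sequence[str], unlog: bool
) -> np.ndarray:
    sub = subset_to_signature(bundle.expression, list(gene_universe), missing="fail")
    v = sub.values
    if unlog:
        v = np.exp2(v)
    if np.any(v <= 0):
        raise ValueError("ratio-score training needs positive intensities")
    return v


def _masks_to_score(
    gene_universe: Sequence[str], num_mask: np.ndarray, den_mask: np.ndarray
) -> RatioScore:
    genes = list(gene_universe)
    return RatioScore(
        [g for g, m in zip(genes, num_mask) if m],
        [g for g, m in zip(genes, den_mask) if m],
    )


def local_search_score(
    train_bundle: CohortBundle,
    test_bundle: CohortBundle,
    gene_universe: Sequence[str],
    seed: int = 0,
    unlog: bool = True,
) -> tuple[RatioScore, float, float]:
    """One seeded random start + greedy local search.

    Returns the locally optimal score with its training and test
    sensitivities at zero false-positive rate. Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    G = len(gene_universe)
    Vtr = _linear_values(train_bundle, gene_universe, unlog)
    Vte = _linear_values(test_bundle, gene_universe, unlog)
    pos_tr = train_bundle.positive_mask()
    pos_te = test_bundle.positive_mask()
    num_mask = rng.random(G) < 0.5
    den_mask = rng.random(G) < 0.5
    # a useful start has something in both sums
    if not num_mask.any():
        num_mask[int(rng.integers(G))] = True
    if not den_mask.any():
        den_mask[int(rng.integers(G))] = True
    num_mask, den_mask, train_sens = _search_from(Vtr, pos_tr, num_mask, den_mask)
    score = _masks_to_score(gene_universe, num_mask, den_mask)
    test_scores = (num_mask @ Vte) / (den_mask @ Vte)
    test_sens = float(sensitivity_at_zero_fpr(test_scores, pos_te))
    return score, float(train_sens), test_sens


def train_score_classifier(
    bundle: CohortBundle,
    gene_universe: Sequence[str],
    n_restarts: int = 100,
    seed: int = 0,
    unlog: bool = True,
    folds: int = 1,
) -> RatioScore:
    """Random-restart training of the ratio score on extreme responders.

    One stratified 50/50 train/test split (``folds=2`` additionally swaps
    the two halves and pools the candidates); ``n_restarts`` seeded local
    searches on the training half; the restart with the best test-half
    sensitivity wins. Ties break by higher training sensitivity, then
    smaller total gene count, then restart order.
    """
    extremes = bundle.restrict_to_extremes()
    ss = np.random.SeedSequence(seed)
    split_seed = int(ss.generate_state(1)[0] % (2**31))
    train_ids, test_ids = resample_split(extremes.labels, 0.5, seed=split_seed)
    halves = [(train_ids, test_ids)]
    if folds == 2:
        halves.append((test_ids, train_ids))
    restart_seeds = ss.spawn(n_restarts)
    candidates: list[tuple[float, float, int, int, RatioScore]] = []
    for h, (tr_ids, te_ids) in enumerate(halves):
        tr = extremes.subset_samples(tr_ids)
        te = extremes.subset_samples(te_ids)
        for i in range(n_restarts):
            rs = int(restart_seeds[i].generate_state(1)[0] % (2**31)) + h
            score, train_sens, test_sens = local_search_score(
                tr, te, gene_universe, seed=rs, unlog=unlog
            )
            n_genes = len(score.numerator_genes) + len(score.denominator_genes)
            candidates.append((test_sens, train_sens, -n_genes, -(h * n_restarts + i), score))
    best = max(candidates, key=lambda c: c[:4])
    return best[4]
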