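"""Resampled hill-climbing discovery of a stable response signature.

The discovery procedure asks not "which genes are differentially expressed"
but "which genes keep earning their place in a classifier whose objective is
sensitivity at zero false positives". One repetition consists of

1. a stratified random split of the extreme responders into a 3/4 training
   and 1/4 test set,
2. a Welch two-sample t differential-expression ranking on the training
   half, keeping the top ``pool_size`` genes as candidates, and
3. greedy forward hill climbing over the candidates: at each step the gene
   whose addition most improves the trained SVM's zero-false-positive
   sensitivity on the held-out test set is added, until no addition strictly
   improves.

Across many repetitions the per-gene selection frequency is compared with a
binomial null whose rate is the mean selected-set size divided by the pool
size; genes selected significantly more often than that form the signature.
Everything is a pure function of (data, configuration, master seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._linsvm import fit_linear_svm
from .core_data import CohortBundle, ExpressionMatrix, ResponseLabel
from .metrics import sensitivity_at_zero_fpr

__all__ = [
    "SignatureResult",
    "resample_split",
    "differential_expression",
    "hill_climb_select",
    "selection_significance",
    "discover_signature",
]


def resample_split(
    labels: list[ResponseLabel], train_fraction: float = 0.75, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Stratified random split of positive/negative samples.

    Both classes appear in both halves; deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for cls in ("positive", "negative"):
        ids = [l.sample_id for l in labels if l.label == cls]
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} needs >= 2 samples, got {len(ids)}")
        perm = rng.permutation(len(ids))
        n_train = int(round(train_fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train_ids.extend(ids[i] for i in perm[:n_train])
        test_ids.extend(ids[i] for i in perm[n_train:])
    return train_ids, test_ids


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch t between sample groups ``a`` and ``b`` (genes x samples)."""
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    degenerate = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, diff / np.sqrt(np.where(degenerate, 1.0, se2)))
        df = np.where(
            degenerate,
            1.0,
            se2**2
            / (np.where(v1 > 0, (v1 / n1) ** 2 / (n1 - 1), 0.0)
               + np.where(v2 > 0, (v2 / n2) ** 2 / (n2 - 1), 0.0) + 1e-300),
        )
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, 1.0, p)
    return t, p, degenerate


def differential_expression(matrix: ExpressionMatrix, train_labels) -> pd.DataFrame:
    """Welch two-sample t per gene, positives vs negatives, ranked by p.

    ``train_labels`` is a positive-mask (or label strings) aligned to the
    matrix columns. Genes with zero variance in both groups get t = 0,
    p = 1 and a ``degenerate`` flag. Ties in p break by |t| descending, then
    original row order.
    """
    lab = np.asarray(train_labels)
    pos = lab == "positive" if lab.dtype.kind in "OUS" else lab.astype(bool)
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present in the training set")
    t, p, degenerate = _welch(matrix.values[:, pos], matrix.values[:, ~pos])
    df = pd.DataFrame({
        "gene_symbol": matrix.gene_symbols,
        "probe_id": matrix.probe_ids,
        "t": t,
        "p_value": p,
        "degenerate": degenerate,
        "row": np.arange(matrix.n_probes),
    })
    df["abs_t"] = np.abs(df["t"])
    df = df.sort_values(
        ["p_value", "abs_t", "row"], ascending=[True, False, True], kind="mergesort"
    ).drop(columns="abs_t").reset_index(drop=True)
    return df


def _objective(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, yte: np.ndarray,
    feats: list[int], C: float,
) -> float:
    w, b = fit_linear_svm(Xtr[:, feats], ytr, C=C, tol=1e-6, max_epochs=2000)
    scores = Xte[:, feats] @ w + b
    return sensitivity_at_zero_fpr(scores, yte)


def _hill_climb(
    Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, yte: np.ndarray,
    pool: list[int], C: float = 1.0, allow_swap: bool = False,
) -> tuple[list[int], float]:
    """Greedy forward selection over pre-standardized column indices."""
    selected: list[int] = []
    best = 0.0
    while True:
        best_move = None
        best_obj = best
        for c in pool:
            if c in selected:
                continue
            obj = _objective(Xtr, ytr, Xte, yte, selected + [c], C)
            if obj > best_obj:
                best_obj, best_move = obj, ("add", c, None)
        if allow_swap and selected:
            for s in selected:
                for c in pool:
                    if c in selected:
                        continue
                    feats = [c if f == s else f for f in selected]
                    obj = _objective(Xtr, ytr, Xte, yte, feats, C)
                    if obj > best_obj:
                        best_obj, best_move = obj, ("swap", c, s)
        if best_move is None:
            return selected, best
        kind, c, s = best_move
        if kind == "add":
            selected.append(c)
        else:
            selected[selected.index(s)] = c
        best = best_obj


def hill_climb_select(
    train_bundle: CohortBundle,
    test_bundle: CohortBundle,
    candidate_pool: list[str],
    C: float = 1.0,
    allow_swap: bool = False,
) -> tuple[list[str], float]:
    """Hill-climbing feature selection at the bundle level.

    ``candidate_pool`` is an ordered gene-symbol list (differential-
    expression rank order is the conventional input); earlier genes win
    ties. Returns the selected symbols and the achieved test objective
    (sensitivity at zero false-positive rate). With nothing improving on the
    empty set, returns ``([], 0.0)``.
    """
    sym_to_row = {s: i for i, s in enumerate(train_bundle.expression.gene_symbols)}
    pool_rows = [sym_to_row[s] for s in candidate_pool]
    ytr = train_bundle.positive_mask()
    yte = test_bundle.positive_mask()
    Xtr = train_bundle.expression.values.T
    Xte = test_bundle.expression.values.T
    means = Xtr.mean(axis=0)
    sds = Xtr.std(axis=0, ddof=0)
    sds = np.where(sds > 0, sds, 1.0)
    Xtr_s = (Xtr - means) / sds
    Xte_s = (Xte - means) / sds
    rows, obj = _hill_climb(Xtr_s, ytr, Xte_s, yte, pool_rows, C, allow_swap)
    symbols = [train_bundle.expression.gene_symbols[r] for r in rows]
    return symbols, obj


def selection_significance(
    selection_count, n_repetitions: int, null_rate: float
) -> np.ndarray:
    """Upper-tail exact binomial p-value of each gene's selection count."""
    if not 0 < null_rate < 1:
        raise ValueError("null_rate must be in (0, 1)")
    counts = np.asarray(selection_count, dtype=int)
    return stats.binom.sf(counts - 1, n_repetitions, null_rate)


@dataclass
class SignatureResult:
    """Aggregate of a full discovery run."""

    gene_symbols: list[str]
    selection_count: np.ndarray
    n_repetitions: int
    null_rate: float
    p_value: np.ndarray
    signature: list[str]
    records: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "n_repetitions": self.n_repetitions,
            "null_rate": self.null_rate,
            "signature": list(self.signature),
            "genes": [
                {"gene_symbol": g, "selection_count": int(c), "p_value": float(p)}
                for g, c, p in zip(self.gene_symbols, self.selection_count, self.p_value)
                if c > 0
            ],
            "records": self.records,
        }


def discover_signature(
    bundle: CohortBundle,
    n_repetitions: int = 500,
    alpha: float = 0.05,
    pool_size: int = 100,
    train_fraction: float = 0.75,
    C: float = 1.0,
    allow_swap: bool = False,
    seed: int = 0,
) -> SignatureResult:
    """Run the full resampled hill-climbing discovery.

    Repeats split -> differential expression -> hill climbing
    ``n_repetitions`` times, then keeps genes whose selection frequency beats
    the binomial null (rate = mean selected-set size / pool size) at
    ``alpha``. Reproducible from the master seed; per-repetition seeds are
    spawned by counter so results do not depend on execution order.
    """
    extremes = bundle.restrict_to_extremes()
    if n_repetitions < 2:
        warnings.warn(
            "fewer than 2 repetitions: selection frequencies are degenerate "
            "and the signature will be empty",
            UserWarning,
            stacklevel=2,
        )
    expr = extremes.expression
    symbols = expr.gene_symbols
    sym_index = {s: i for i, s in enumerate(symbols)}
    y_all = extremes.positive_mask()
    X_all = expr.values  # genes x samples
    sample_index = {s: j for j, s in enumerate(expr.sample_ids)}

    counts = np.zeros(expr.n_probes, dtype=int)
    records: list[dict] = []
    child_seeds = np.random.SeedSequence(seed).spawn(n_repetitions)
    for r in range(n_repetitions):
        rep_seed = child_seeds[r]
        split_seed = int(rep_seed.generate_state(1)[0] % (2**31))
        train_ids, test_ids = resample_split(
            extremes.labels, train_fraction, seed=split_seed
        )
        tr = np.array([sample_index[s] for s in train_ids])
        te = np.array([sample_index[s] for s in test_ids])
        ytr, yte = y_all[tr], y_all[te]
        t, p, _ = _welch(X_all[:, tr][:, ytr], X_all[:, tr][:, ~ytr])
        order = np.lexsort((np.arange(len(p)), -np.abs(t), p))
        pool_rows = order[:pool_size].tolist()

        Xtr = X_all[:, tr].T
        Xte = X_all[:, te].T
        means = Xtr.mean(axis=0)
        sds = Xtr.std(axis=0, ddof=0)
        sds = np.where(sds > 0, sds, 1.0)
        sel_rows, obj = _hill_climb(
            (Xtr - means) / sds, ytr, (Xte - means) / sds, yte,
            pool_rows, C, allow_swap,
        )
        counts[sel_rows] += 1
        records.append({
            "repetition": r,
            "split_seed": split_seed,
            "pool": [symbols[i] for i in pool_rows],
            "selected": [symbols[i] for i in sel_rows],
            "test_sensitivity": obj,
        })

    mean_selected = float(np.mean([len(rec["selected"]) for rec in records]))
    null_rate = mean_selected / pool_size if pool_size > 0 else 0.0
    if n_repetitions >= 2 and 0 < null_rate < 1:
        p_values = selection_significance(counts, n_repetitions, null_rate)
        sig_rows = np.flatnonzero(p_values < alpha)
        sig_order = sig_rows[np.lexsort((sig_rows, -counts[sig_rows]))]
        signature = [symbols[i] for i in sig_order]
    else:
        p_values = np.ones(expr.n_probes)
        signature = []
    return SignatureResult(
        gene_symbols=list(symbols),
        selection_count=counts,
        n_repetitions=n_repetitions,
        null_rate=null_rate,
        p_value=p_values,
        signature=signature,
        records=records,
    )
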