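"""Data model for expression cohorts, response labels, and TSV I/O.

The central objects are :class:`ExpressionMatrix` (log2 intensities,
transcripts x samples), :class:`SampleAnnotation` (clinical record with the
tumour regression grade, TRG, in percent), and :class:`CohortBundle` tying
them together with derived :class:`ResponseLabel` records.

Response labelling follows the extreme-response design used for classifier
discovery: *positive* means pathological complete response (TRG = 100%,
or a declared ordinal grade mapping to complete response), *negative* means
poor response (TRG < 45%), everything in between is *intermediate*, and
samples without any usable regression information are *unknown*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GENE_ALIASES",
    "ExpressionMatrix",
    "SampleAnnotation",
    "ResponseLabel",
    "CohortBundle",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "derive_labels",
    "subset_to_signature",
    "canonical_symbol",
]

#: Legacy -> current HGNC symbol aliases for the signature genes whose
#: published names differ between the transcript table and the score formula.
GENE_ALIASES: dict[str, str] = {
    "KIAA1598": "SHTN1",
    "C19orf51": "DNAAF3",
    "C20orf26": "CFAP61",
    "CASC5": "KNL1",
}

LabelValue = Literal["positive", "negative", "intermediate", "unknown"]


def canonical_symbol(symbol: str, alias_map: Mapping[str, str] | None = None) -> str:
    """Map a (possibly legacy) gene symbol to its canonical name."""
    amap = GENE_ALIASES if alias_map is None else alias_map
    return amap.get(symbol, symbol)


@dataclass
class ExpressionMatrix:
    """Log2 expression intensities, rows = transcripts, columns = samples."""

    values: np.ndarray
    probe_ids: list[str]
    gene_symbols: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.gene_symbols = [str(g) for g in self.gene_symbols]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        n_rows, n_cols = self.values.shape
        if n_rows < 1 or n_cols < 1:
            raise ValueError("expression matrix must have >= 1 row and column")
        if len(self.probe_ids) != n_rows or len(self.gene_symbols) != n_rows:
            raise ValueError("probe/gene annotation length does not match rows")
        if len(self.sample_ids) != n_cols:
            raise ValueError("sample id count does not match columns")
        for name, ids in (("probe_id", self.probe_ids), ("sample_id", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {name}: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at probe {self.probe_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            list(self.probe_ids),
            list(self.gene_symbols),
            list(self.sample_ids),
        )

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Same annotation, new value matrix (shape must match)."""
        return ExpressionMatrix(
            values, list(self.probe_ids), list(self.gene_symbols), list(self.sample_ids)
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        cols = [index[s] for s in sample_ids]
        return ExpressionMatrix(
            self.values[:, cols],
            list(self.probe_ids),
            list(self.gene_symbols),
            [self.sample_ids[c] for c in cols],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.sample_ids)
        df.insert(0, "gene_symbol", self.gene_symbols)
        df.insert(0, "probe_id", self.probe_ids)
        return df


def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


@dataclass
class SampleAnnotation:
    """Per-sample clinical record.

    ``trg_percent`` is the tumour regression grade in percent (0-100, higher
    means more regression; 100 = complete response). ``trg_ordinal`` carries a
    Dworak/Mandard-style ordinal grade when the percent scale is unavailable.
    Survival follow-up is optional; time units are arbitrary but must be
    consistent within a cohort.
    """

    sample_id: str
    trg_percent: float | None = None
    trg_ordinal: int | None = None
    cohort_label: str = ""
    os_time: float | None = None
    os_event: int | None = None
    dfs_time: float | None = None
    dfs_event: int | None = None
    sex: str | None = None
    age: float | None = None

    def __post_init__(self) -> None:
        if self.trg_percent is not None:
            if not 0.0 <= float(self.trg_percent) <= 100.0:
                raise ValueError(
                    f"trg_percent out of [0,100] for {self.sample_id!r}: {self.trg_percent}"
                )
        for name in ("os_event", "dfs_event"):
            v = getattr(self, name)
            if v is not None and int(v) not in (0, 1):
                raise ValueError(f"{name} must be 0/1 for {self.sample_id!r}: {v}")
        for name in ("os_time", "dfs_time"):
            v = getattr(self, name)
            if v is not None and float(v) < 0:
                raise ValueError(f"{name} must be >= 0 for {self.sample_id!r}: {v}")


@dataclass(frozen=True)
class ResponseLabel:
    sample_id: str
    label: LabelValue


@dataclass
class CohortBundle:
    """Expression + annotation + response labels over one sample set."""

    expression: ExpressionMatrix
    annotation: list[SampleAnnotation]
    labels: list[ResponseLabel]

    def __post_init__(self) -> None:
        s_expr = set(self.expression.sample_ids)
        s_ann = {a.sample_id for a in self.annotation}
        s_lab = {l.sample_id for l in self.labels}
        if not (s_expr == s_ann == s_lab):
            raise ValueError(
                "sample sets of expression, annotation and labels differ: "
                f"{sorted(s_expr ^ s_ann) + sorted(s_expr ^ s_lab)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.sample_ids)

    def label_map(self) -> dict[str, LabelValue]:
        return {l.sample_id: l.label for l in self.labels}

    def annotation_map(self) -> dict[str, SampleAnnotation]:
        return {a.sample_id: a for a in self.annotation}

    def label_array(self) -> np.ndarray:
        """Labels aligned to expression columns."""
        lm = self.label_map()
        return np.array([lm[s] for s in self.expression.sample_ids], dtype=object)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CohortBundle":
        keep = set(sample_ids)
        lm = self.label_map()
        am = self.annotation_map()
        return CohortBundle(
            expression=self.expression.subset_samples(list(sample_ids)),
            annotation=[am[s] for s in sample_ids],
            labels=[ResponseLabel(s, lm[s]) for s in sample_ids],
        )

    def restrict_to_extremes(self) -> "CohortBundle":
        """Keep only positive (pCR) and negative (poor response) samples."""
        lm = self.label_map()
        keep = [s for s in self.expression.sample_ids if lm[s] in ("positive", "negative")]
        return self.subset_samples(keep)

    def positive_mask(self) -> np.ndarray:
        return self.label_array() == "positive"


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a ``probe_id<TAB>gene_symbol<TAB>S1<TAB>...`` expression table.

    Raises with the offending identifier on duplicates and with row/column
    coordinates on non-numeric cells.
    """
    # header parsed without pandas' duplicate-name mangling
    raw = pd.read_csv(path, sep="\t", dtype=str, header=None, keep_default_na=False)
    if raw.shape[1] < 3:
        raise ValueError("expression TSV needs probe_id, gene_symbol and >= 1 sample")
    header = [str(c) for c in raw.iloc[0]]
    sample_ids = header[2:]
    dup = _first_duplicate(sample_ids)
    if dup is not None:
        raise ValueError(f"duplicate sample_id: {dup!r}")
    df = raw.iloc[1:].reset_index(drop=True)
    df.columns = header
    probe_ids = df.iloc[:, 0].tolist()
    gene_symbols = df.iloc[:, 1].tolist()
    values = np.empty((len(df), len(sample_ids)), dtype=float)
    for j, col in enumerate(df.columns[2:]):
        raw = df[col].to_numpy(dtype=object)
        try:
            values[:, j] = raw.astype(np.float64)  # exact, correctly rounded
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            i = int(np.flatnonzero(bad.isna().to_numpy())[0])
            raise ValueError(
                f"non-numeric value {df[col].iloc[i]!r} at probe {probe_ids[i]!r} "
                f"(row {i}), sample {sample_ids[j]!r} (column {j})"
            ) from None
    return ExpressionMatrix(values, probe_ids, gene_symbols, sample_ids)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    """Write the TSV dialect read by :func:`read_expression_tsv` (lossless)."""
    # %.17g preserves float64 exactly on round trip
    matrix.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


_ANNOTATION_COLUMNS = [
    "sample_id", "trg_percent", "trg_ordinal", "cohort_label",
    "os_time", "os_event", "dfs_time", "dfs_event", "sex", "age",
]


def read_annotation_tsv(path) -> list[SampleAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValueError("annotation TSV must have a sample_id column")
    out = []
    for _, row in df.iterrows():
        def get(name, conv):
            v = row.get(name, "")
            return conv(v) if v not in ("", None) else None
        out.append(SampleAnnotation(
            sample_id=str(row["sample_id"]),
            trg_percent=get("trg_percent", float),
            trg_ordinal=get("trg_ordinal", lambda v: int(float(v))),
            cohort_label=str(row.get("cohort_label", "") or ""),
            os_time=get("os_time", float),
            os_event=get("os_event", lambda v: int(float(v))),
            dfs_time=get("dfs_time", float),
            dfs_event=get("dfs_event", lambda v: int(float(v))),
            sex=(str(row["sex"]) if row.get("sex", "") != "" else None),
            age=get("age", float),
        ))
    return out


def write_annotation_tsv(annotation: Sequence[SampleAnnotation], path) -> None:
    rows = []
    for a in annotation:
        rows.append({c: getattr(a, c) for c in _ANNOTATION_COLUMNS})
    pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# Response labelling
# ---------------------------------------------------------------------------

def derive_labels(
    annotation: Sequence[SampleAnnotation],
    complete_threshold: float = 100.0,
    poor_threshold: float = 45.0,
    ordinal_map: Mapping[int, LabelValue] | None = None,
) -> list[ResponseLabel]:
    """Assign positive/negative/intermediate/unknown response labels.

    A sample is *positive* (pCR) when ``trg_percent >= complete_threshold``
    (the default, 100, makes this TRG = 100 exactly), *negative* when
    ``trg_percent < poor_threshold`` and *intermediate* otherwise. Samples
    with missing TRG percent fall back to ``ordinal_map`` applied to the
    ordinal grade (e.g. ``{4: "positive"}`` for Dworak grade 4 = complete
    response); if that does not resolve either, the label is *unknown*.
    """
    if not 0 < poor_threshold <= complete_threshold <= 100:
        raise ValueError("thresholds must satisfy 0 < poor <= complete <= 100")
    out: list[ResponseLabel] = []
    for a in annotation:
        if a.trg_percent is not None:
            t = float(a.trg_percent)
            if t >= complete_threshold:
                lab: LabelValue = "positive"
            elif t < poor_threshold:
                lab = "negative"
            else:
                lab = "intermediate"
        elif a.trg_ordinal is not None and ordinal_map and a.trg_ordinal in ordinal_map:
            lab = ordinal_map[a.trg_ordinal]
        else:
            lab = "unknown"
        out.append(ResponseLabel(a.sample_id, lab))
    return out


# ---------------------------------------------------------------------------
# Signature subsetting
# ---------------------------------------------------------------------------

def subset_to_signature(
    matrix: ExpressionMatrix,
    gene_list: Sequence[str],
    alias_map: Mapping[str, str] | None = None,
    missing: Literal["fail", "drop", "impute-reference-mean"] = "fail",
    reference_means: Mapping[str, float] | None = None,
) -> ExpressionMatrix:
    """Extract signature rows by gene symbol, resolving legacy aliases.

    Both the requested symbols and the matrix's symbols are canonicalised
    through ``alias_map`` (default: the shipped legacy-name table), so a
    request for ``C20orf26`` finds a row annotated ``CFAP61`` and vice versa.
    Rows are returned in ``gene_list`` order; multiple probes mapping to the
    same symbol are collapsed by their per-sample mean. Missing genes are
    handled per ``missing``: hard error, drop with a warning, or impute a
    constant row from ``reference_means``.
    """
    amap = GENE_ALIASES if alias_map is None else dict(alias_map)
    canon_rows: dict[str, list[int]] = {}
    for i, sym in enumerate(matrix.gene_symbols):
        canon_rows.setdefault(canonical_symbol(sym, amap), []).append(i)

    ref_by_canon: dict[str, float] = {}
    if reference_means is not None:
        for k, v in reference_means.items():
            ref_by_canon[canonical_symbol(k, amap)] = float(v)

    values_rows: list[np.ndarray] = []
    probe_ids: list[str] = []
    gene_symbols: list[str] = []
    absent: list[str] = []
    for requested in gene_list:
        canon = canonical_symbol(requested, amap)
        rows = canon_rows.get(canon)
        if rows:
            if len(rows) == 1:
                values_rows.append(matrix.values[rows[0]])
                probe_ids.append(matrix.probe_ids[rows[0]])
            else:
                values_rows.append(matrix.values[rows].mean(axis=0))
                probe_ids.append(";".join(sorted(matrix.probe_ids[r] for r in rows)))
            gene_symbols.append(requested)
            continue
        absent.append(requested)
        if missing == "impute-reference-mean":
            if canon not in ref_by_canon:
                raise ValueError(f"no reference mean available to impute {requested!r}")
            values_rows.append(np.full(matrix.n_samples, ref_by_canon[canon]))
            probe_ids.append(f"imputed:{requested}")
            gene_symbols.append(requested)
    if absent:
        if missing == "fail":
            raise KeyError(f"signature genes absent from matrix: {absent}")
        warnings.warn(
            f"signature genes absent from matrix ({missing}): {absent}",
            UserWarning,
            stacklevel=2,
        )
    if not values_rows:
        return _EmptySignatureMatrix(matrix.sample_ids)  # type: ignore[return-value]
    return ExpressionMatrix(
        np.vstack(values_rows), probe_ids, gene_symbols, matrix.sample_ids
    )


class _EmptySignatureMatrix:
    """Degenerate 0-row result of subsetting when every gene was dropped."""

    def __init__(self, sample_ids: Sequence[str]):
        self.values = np.empty((0, len(sample_ids)))
        self.probe_ids: list[str] = []
        self.gene_symbols: list[str] = []
        self.sample_ids = list(sample_ids)
        self.n_probes = 0
        self.n_samples = len(sample_ids)
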