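"""Reading, normalizing, and filtering temporal expression matrices.

The analysis-ready object is :class:`ExpressionMatrix`: a genes x samples
table of fluorescence intensities where every sample carries Zeitgeber-time
(ZT, hours since lights-on) and technical-replicate metadata.  Sample
columns are labelled ``ZT<hh>_r<k>`` (e.g. ``ZT04_r2``) in the on-disk
tab-separated format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "quantile_normalize",
    "filter_background",
    "collapse_replicates",
]

_SAMPLE_RE = re.compile(r"^ZT(\d+(?:\.\d+)?)_r(\d+)$")


def sample_label(zt: float, replicate: int) -> str:
    if float(zt).is_integer():
        return f"ZT{int(zt):02d}_r{int(replicate)}"
    return f"ZT{zt:g}_r{int(replicate)}"


@dataclass
class ExpressionMatrix:
    """Genes x samples intensity matrix with ZT/replicate metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id; one column per sample.
    zt
        Zeitgeber time (hours) of each sample column.
    replicate
        Technical replicate index of each sample column.
    log2
        Whether ``values`` are on the log2 scale (raw fluorescence if False).
    """

    values: pd.DataFrame
    zt: np.ndarray
    replicate: np.ndarray
    log2: bool = False

    def __post_init__(self) -> None:
        self.zt = np.asarray(self.zt, dtype=float)
        self.replicate = np.asarray(self.replicate, dtype=int)
        if self.values.shape[1] != len(self.zt) or len(self.zt) != len(self.replicate):
            raise ValueError("sample metadata length does not match column count")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def timepoints(self) -> np.ndarray:
        """Sorted unique ZT hours."""
        return np.unique(self.zt)

    def copy_with(self, values: pd.DataFrame, **kw) -> "ExpressionMatrix":
        meta = dict(zt=self.zt.copy(), replicate=self.replicate.copy(), log2=self.log2)
        meta.update(kw)
        return ExpressionMatrix(values, **meta)

    def to_log2(self) -> "ExpressionMatrix":
        if self.log2:
            return self
        vals = self.values.where(self.values > 0)
        if vals.isna().any().any():
            raise ValueError("non-positive intensities cannot be log2 transformed")
        return self.copy_with(np.log2(self.values), log2=True)


def parse_sample_label(label: str) -> tuple[float, int]:
    m = _SAMPLE_RE.match(label)
    if m is None:
        raise ValueError(f"unparseable sample label: {label!r} (expected ZT<h>_r<k>)")
    return float(m.group(1)), int(m.group(2))


def read_expression(path, log2: bool = False) -> ExpressionMatrix:
    """Read a tab-separated genes x samples matrix.

    The header row holds sample labels ``ZT<hh>_r<k>``; the first column
    holds unique gene ids.  Raises on duplicate gene ids, ragged rows, or
    unparseable sample labels.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups[:5]}")
    if df.isna().any().any():
        raise ValueError(f"missing values (ragged rows?) in {path}")
    meta = [parse_sample_label(c) for c in df.columns]
    zt = np.array([m[0] for m in meta])
    rep = np.array([m[1] for m in meta])
    return ExpressionMatrix(df.astype(float), zt=zt, replicate=rep, log2=log2)


def write_expression(m: ExpressionMatrix, path) -> None:
    df = m.values.copy()
    df.columns = [sample_label(z, r) for z, r in zip(m.zt, m.replicate)]
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize all sample columns to a common distribution.

    Every column's sorted values are replaced by the per-rank mean of the
    column-sorted input; ties within a column receive the mean of the target
    values of their occupied ranks.  Idempotent and rank-preserving within
    columns.
    """
    x = m.values.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in expression matrix")
    n, p = x.shape
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(p):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = target.copy()
        # ties: average the target values over each tied run
        sorted_col = col[order]
        i = 0
        while i < n:
            k = i
            while k + 1 < n and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            if k > i:
                ranked[i : k + 1] = ranked[i : k + 1].mean()
            i = k + 1
        out[order, j] = ranked
    vals = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return m.copy_with(vals)


def filter_background(
    m: ExpressionMatrix, cutoff: float = 136.5
) -> tuple[ExpressionMatrix, dict]:
    """Drop genes that never exceed the background fluorescence cutoff.

    A gene is retained iff its maximum over all samples is > ``cutoff``.
    Operates on raw (non-log) intensities.  Returns the filtered matrix and
    a report dict with kept/removed counts.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if m.log2:
        raise ValueError("background filter operates on raw-scale intensities")
    keep = (m.values.to_numpy() > cutoff).any(axis=1)
    report = {
        "cutoff": float(cutoff),
        "n_input": int(m.n_genes),
        "n_kept": int(keep.sum()),
        "n_removed": int((~keep).sum()),
    }
    return m.copy_with(m.values.loc[keep]), report


def collapse_replicates(m: ExpressionMatrix) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Average technical replicates into one column per timepoint.

    Returns the collapsed matrix (replicate index 1 everywhere) and a
    DataFrame of per-timepoint standard errors of the mean.
    """
    tps = m.timepoints
    means = np.empty((m.n_genes, len(tps)))
    sems = np.empty_like(means)
    for j, t in enumerate(tps):
        cols = m.values.loc[:, m.zt == t].to_numpy()
        if cols.shape[1] == 0:
            raise ValueError(f"missing timepoint ZT{t}")
        means[:, j] = cols.mean(axis=1)
        sems[:, j] = (
            cols.std(axis=1, ddof=1) / np.sqrt(cols.shape[1])
            if cols.shape[1] > 1
            else 0.0
        )
    labels = [sample_label(t, 1) for t in tps]
    vals = pd.DataFrame(means, index=m.values.index, columns=labels)
    sem_df = pd.DataFrame(sems, index=m.values.index, columns=labels)
    collapsed = ExpressionMatrix(
        vals, zt=tps, replicate=np.ones(len(tps), dtype=int), log2=m.log2
    )
    return collapsed, sem_df
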