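"""Binned ChIP signal extraction and median-of-ratios normalization.

Signal around each binding site is summarised in a fixed window (default
±5 kbp, anchored at the site midpoint) fractioned into consecutive
non-overlapping bins (default 50 bp, i.e. 200 bins per site).  Counts for
all (site, bin) rows across experiments form a :class:`BinCountMatrix`.

Normalization is the median-of-ratios size-factor estimator applied to this
matrix: per row j the geometric mean G_j across experiments is taken over
rows with all counts positive, each row is divided by G_j, and the size
factor of experiment i is the median over rows of those ratios.  Dividing a
column by its size factor puts all experiments on a common scale without
assuming equal total signal — robust to a minority of bins with genuine
occupancy differences, exactly the property that makes the estimator the
standard for count data.

The two-step strategy normalizes (1) each factor's datasets across contexts
(then averages within context), enabling inter-context comparison of one
factor, and (2) the per-factor averages within each context, enabling
intra-context comparison between factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GenomeLayout, Interval, IntervalSet


# ---------------------------------------------------------------------------
# Bin scheme and count matrix containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinScheme:
    """Window/bin geometry around a site midpoint.

    half_window : bp on each side of the site center (default 5000)
    bin_size    : bp per bin (default 50); must divide the full window
    """

    half_window: int = 5000
    bin_size: int = 50

    def __post_init__(self) -> None:
        if self.half_window <= 0 or self.bin_size <= 0:
            raise ValueError("half_window and bin_size must be positive")
        if (2 * self.half_window) % self.bin_size != 0:
            raise ValueError(
                f"bin_size {self.bin_size} does not divide window {2 * self.half_window}")

    @property
    def n_bins(self) -> int:
        return (2 * self.half_window) // self.bin_size


@dataclass
class BinCountMatrix:
    """Counts per (site, bin) row and experiment column, with metadata.

    values      : (n_rows, n_experiments) non-negative array
    row_meta    : DataFrame with columns site_id, bin_index (+ genomic span)
    col_meta    : DataFrame with columns label, factor, context
    size_factors: recorded when ``normalized`` is set
    """

    values: np.ndarray
    row_meta: pd.DataFrame
    col_meta: pd.DataFrame
    normalized: bool = False
    size_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if len(self.row_meta) != self.values.shape[0]:
            raise ValueError("row_meta length does not match matrix rows")
        if len(self.col_meta) != self.values.shape[1]:
            raise ValueError("col_meta length does not match matrix columns")
        if (self.values < 0).any():
            raise ValueError("negative counts")
        if self.normalized and self.size_factors is None:
            raise ValueError("normalized matrix must record its size factors")

    @property
    def n_experiments(self) -> int:
        return self.values.shape[1]

    @property
    def labels(self) -> list[str]:
        return list(self.col_meta["label"])

    @property
    def site_ids(self) -> list[str]:
        return list(dict.fromkeys(self.row_meta["site_id"]))

    @property
    def n_bins(self) -> int:
        return int(self.row_meta["bin_index"].max()) + 1 if len(self.row_meta) else 0

    def column(self, label: str) -> np.ndarray:
        return self.values[:, self.labels.index(label)]

    def site_profiles(self, label: str) -> np.ndarray:
        """(n_sites, n_bins) view of one experiment, sites in row order."""
        return self.column(label).reshape(len(self.site_ids), self.n_bins)

    def same_rows(self, other: "BinCountMatrix") -> bool:
        a = self.row_meta[["site_id", "bin_index"]].reset_index(drop=True)
        b = other.row_meta[["site_id", "bin_index"]].reset_index(drop=True)
        return a.equals(b)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.concat(
            [self.row_meta[["site_id", "bin_index"]].reset_index(drop=True),
             pd.DataFrame(self.values, columns=self.labels)], axis=1)
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 col_meta: pd.DataFrame | None = None) -> "BinCountMatrix":
        df = pd.read_csv(path, sep="\t")
        if list(df.columns[:2]) != ["site_id", "bin_index"]:
            raise ValueError("matrix TSV must start with site_id and bin_index columns")
        labels = list(df.columns[2:])
        if col_meta is None:
            col_meta = pd.DataFrame({"label": labels, "factor": labels,
                                     "context": [""] * len(labels)})
        return cls(df[labels].to_numpy(dtype=float),
                   df[["site_id", "bin_index"]].copy(), col_meta.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def _read_anchors(reads: IntervalSet, anchor: str) -> dict[str, np.ndarray]:
    """Sorted per-chromosome anchor positions for placement counting."""
    pos: dict[str, list[int]] = {}
    for iv in reads:
        if anchor == "midpoint":
            p = iv.center
        elif anchor == "fiveprime":
            p = iv.start
        else:
            raise ValueError(f"unknown read anchor {anchor!r}")
        pos.setdefault(iv.chrom, []).append(p)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in pos.items()}


def _site_windows(
    sites: IntervalSet,
    half_window: int,
    layout: GenomeLayout | None,
) -> tuple[list[Interval], list[str], int]:
    """Sites whose full window fits the genome; out-of-bounds sites are dropped."""
    kept: list[Interval] = []
    ids: list[str] = []
    dropped = 0
    for i, iv in enumerate(sites):
        c = iv.center
        lo, hi = c - half_window, c + half_window
        if lo < 0 or (layout is not None and hi > layout.length_of(iv.chrom)):
            dropped += 1
            continue
        kept.append(iv)
        ids.append(iv.name if iv.name is not None else f"site_{i + 1}")
    if dropped:
        warnings.warn(f"dropped {dropped} site(s) whose window exceeds chromosome bounds",
                      stacklevel=3)
    return kept, ids, dropped


def count_in_bins(
    reads: Mapping[str, IntervalSet],
    sites: IntervalSet,
    scheme: BinScheme = BinScheme(),
    *,
    layout: GenomeLayout | None = None,
    read_anchor: str = "midpoint",
    col_meta: pd.DataFrame | None = None,
) -> BinCountMatrix:
    """Count read placements per (site, bin) for each experiment.

    ``reads`` maps experiment label → placements; a placement falls in bin
    b of a site iff its anchor lies in ``[window_start + b·bin, window_start
    + (b+1)·bin)`` with the window ``[center − half_window, center +
    half_window)`` anchored at the site midpoint.
    """
    if len(sites) == 0:
        raise ValueError("empty site list")
    if not reads:
        raise ValueError("no read sets given")
    kept, ids, _ = _site_windows(sites, scheme.half_window, layout)
    if not kept:
        raise ValueError("no site window fits inside the genome")
    n_bins = scheme.n_bins
    labels = list(reads)

    values = np.zeros((len(kept) * n_bins, len(labels)))
    for e, label in enumerate(labels):
        anchors = _read_anchors(reads[label], read_anchor)
        for s, iv in enumerate(kept):
            pos = anchors.get(iv.chrom)
            if pos is None or not len(pos):
                continue
            lo = iv.center - scheme.half_window
            hi = iv.center + scheme.half_window
            a, b = np.searchsorted(pos, (lo, hi))
            if b > a:
                binned = (pos[a:b] - lo) // scheme.bin_size
                values[s * n_bins:(s + 1) * n_bins, e] += np.bincount(
                    binned, minlength=n_bins)

    row_meta = pd.DataFrame({
        "site_id": np.repeat(ids, n_bins),
        "bin_index": np.tile(np.arange(n_bins), len(kept)),
        "chrom": np.repeat([iv.chrom for iv in kept], n_bins),
    })
    starts = np.concatenate([
        iv.center - scheme.half_window + np.arange(n_bins) * scheme.bin_size
        for iv in kept])
    row_meta["bin_start"] = starts
    row_meta["bin_end"] = starts + scheme.bin_size
    if col_meta is None:
        col_meta = pd.DataFrame({"label": labels, "factor": labels,
                                 "context": [""] * len(labels)})
    return BinCountMatrix(values, row_meta, col_meta.reset_index(drop=True))


def count_in_window(
    reads: IntervalSet,
    sites: IntervalSet,
    half_width: int = 200,
    *,
    layout: GenomeLayout | None = None,
    read_anchor: str = "midpoint",
) -> tuple[np.ndarray, float]:
    """Per-site placement counts in ``[center − half_width, center + half_width)``
    and their mean over sites (the single-window summary used for intensity
    comparisons across conditions)."""
    if len(sites) == 0:
        raise ValueError("empty site list")
    kept, _, _ = _site_windows(sites, half_width, layout)
    if not kept:
        raise ValueError("no site window fits inside the genome")
    anchors = _read_anchors(reads, read_anchor)
    counts = np.zeros(len(kept))
    for s, iv in enumerate(kept):
        pos = anchors.get(iv.chrom)
        if pos is None or not len(pos):
            continue
        a, b = np.searchsorted(pos, (iv.center - half_width, iv.center + half_width))
        counts[s] = b - a
    return counts, float(counts.mean())


# ---------------------------------------------------------------------------
# Median-of-ratios normalization
# ---------------------------------------------------------------------------

def normchip_size_factors(
    m: BinCountMatrix | np.ndarray,
    *,
    pseudocount: float = 0.0,
) -> np.ndarray:
    """Median-of-ratios size factors, one per experiment column.

    G_j = (∏_i M[j,i])^(1/N) over rows with all entries > 0; s_i =
    median_j M[j,i] / G_j.  The geometric mean is computed in log space.
    Rows containing a zero are excluded (their count is logged); pass a
    ``pseudocount`` to include them instead.
    """
    values = m.values if isinstance(m, BinCountMatrix) else np.asarray(m, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("size factors need a matrix with at least 2 experiment columns")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount:
        values = values + pseudocount
    positive = (values > 0).all(axis=1)
    n_excluded = int((~positive).sum())
    if not positive.any():
        raise ValueError(
            "no row with all counts positive; re-run with a pseudocount "
            "(e.g. pseudocount=0.5) or supply deeper counts")
    if n_excluded:
        warnings.warn(f"{n_excluded} row(s) with zeros excluded from size-factor estimation",
                      stacklevel=2)
    pos = values[positive]
    g = np.exp(np.log(pos).mean(axis=1))            # geometric mean per row, log space
    s = np.median(pos / g[:, None], axis=0)         # even count: mean of central pair
    if not (s > 0).all():                           # pragma: no cover - guarded above
        raise ValueError("non-positive size factor")
    return s


def normchip_apply(m: BinCountMatrix, s: np.ndarray) -> BinCountMatrix:
    """Divide each experiment column by its size factor."""
    s = np.asarray(s, dtype=float)
    if s.shape != (m.n_experiments,):
        raise ValueError(f"size-factor vector of length {s.size} for "
                         f"{m.n_experiments} experiments")
    if (s <= 0).any():
        raise ValueError("size factors must be strictly positive")
    return BinCountMatrix(m.values / s[None, :], m.row_meta.copy(), m.col_meta.copy(),
                          normalized=True, size_factors=s.copy())


def normchip(m: BinCountMatrix, *, pseudocount: float = 0.0) -> BinCountMatrix:
    """Estimate size factors and return the normalized matrix."""
    return normchip_apply(m, normchip_size_factors(m, pseudocount=pseudocount))


def average_profiles(
    m: BinCountMatrix,
    groups: Mapping[str, Sequence[str]] | str,
) -> BinCountMatrix:
    """Arithmetic per-row mean of experiment columns within groups.

    ``groups`` maps output label → member column labels, or names a col_meta
    column (e.g. ``"context"``) whose values define the grouping.
    """
    if isinstance(groups, str):
        key = groups
        if key not in m.col_meta.columns:
            raise ValueError(f"col_meta has no column {key!r}")
        mapping: dict[str, list[str]] = {}
        for label, g in zip(m.labels, m.col_meta[key]):
            mapping.setdefault(str(g), []).append(label)
    else:
        mapping = {k: list(v) for k, v in groups.items()}
        unknown = {lab for labs in mapping.values() for lab in labs} - set(m.labels)
        if unknown:
            raise ValueError(f"unknown column labels {sorted(unknown)}")
    out_labels = list(mapping)
    values = np.column_stack([
        m.values[:, [m.labels.index(lab) for lab in mapping[g]]].mean(axis=1)
        for g in out_labels])
    col_meta = pd.DataFrame({"label": out_labels,
                             "factor": out_labels,
                             "context": out_labels})
    return BinCountMatrix(values, m.row_meta.copy(), col_meta,
                          normalized=m.normalized,
                          size_factors=np.ones(len(out_labels)) if m.normalized else None)


def two_step_normalize(m: BinCountMatrix, *, pseudocount: float = 0.0) -> BinCountMatrix:
    """Two-step normalization producing one reference profile per (factor, context).

    Step 1: per factor, size-factor-normalize that factor's datasets across
    all contexts together, then average the normalized profiles within each
    context.  Step 2: per context, size-factor-normalize the per-factor
    averaged profiles against each other.  A factor (or context) with a
    single column skips its scaling step with a warning.
    """
    for col in ("factor", "context"):
        if col not in m.col_meta.columns:
            raise ValueError(f"col_meta must carry a {col!r} column")
    factors = list(dict.fromkeys(m.col_meta["factor"]))
    contexts = list(dict.fromkeys(m.col_meta["context"]))

    # --- step 1: within-factor normalization across contexts, then context averages
    step1_cols: dict[tuple[str, str], np.ndarray] = {}
    for factor in factors:
        idx = [i for i, f in enumerate(m.col_meta["factor"]) if f == factor]
        sub = m.values[:, idx]
        if len(idx) >= 2:
            s = normchip_size_factors(sub, pseudocount=pseudocount)
            sub = sub / s[None, :]
        else:
            warnings.warn(f"factor {factor!r} has a single dataset; step-1 scaling skipped",
                          stacklevel=2)
        ctx_of = [m.col_meta["context"].iloc[i] for i in idx]
        for context in dict.fromkeys(ctx_of):
            cols = [k for k, c in enumerate(ctx_of) if c == context]
            step1_cols[(factor, context)] = sub[:, cols].mean(axis=1)

    # --- step 2: within-context normalization across factors
    out_values: dict[tuple[str, str], np.ndarray] = {}
    for context in contexts:
        keys = [(f, c) for (f, c) in step1_cols if c == context]
        sub = np.column_stack([step1_cols[k] for k in keys])
        if len(keys) >= 2:
            s = normchip_size_factors(sub, pseudocount=pseudocount)
            sub = sub / s[None, :]
        else:
            warnings.warn(f"context {context!r} has a single factor; step-2 scaling skipped",
                          stacklevel=2)
        for k, key in enumerate(keys):
            out_values[key] = sub[:, k]

    ordered = [(f, c) for f in factors for c in contexts if (f, c) in out_values]
    values = np.column_stack([out_values[k] for k in ordered])
    col_meta = pd.DataFrame({
        "label": [f"{f}@{c}" if c != "" else f for f, c in ordered],
        "factor": [f for f, _ in ordered],
        "context": [c for _, c in ordered],
    })
    return BinCountMatrix(values, m.row_meta.copy(), col_meta,
                          normalized=True, size_factors=np.ones(len(ordered)))
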