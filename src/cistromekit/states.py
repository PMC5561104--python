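"""Chromatin-state segmentation overlay: majority assignment and enrichment.

A segmentation (ChromHMM/Spectacle-style dense BED4, state label in the name
column) is consumed, never learned here.  Two complementary summaries:

* :func:`assign_majority_state` labels each site with the state covering the
  largest share of its bases (site-count summaries per subset);
* :func:`state_enrichment` compares, per feature set, the bp-weighted
  observed overlap fraction with each state against the state's share of the
  segmented genome, and Z-standardizes the observed/expected ratios across
  states within the feature row, so enriched and depleted states stand out
  on a common scale.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import BedParseError, Interval, IntervalSet, read_bed, write_bed


@dataclass
class Segmentation:
    """A labeled, non-overlapping genome partition (one state per interval)."""

    intervals: list[Interval]              # name field = state label
    states: list[str]
    state_bp: dict[str, int]

    def __post_init__(self) -> None:
        self.intervals.sort(key=lambda iv: (iv.chrom, iv.start))
        prev: Interval | None = None
        for iv in self.intervals:
            if iv.name is None:
                raise ValueError(f"unlabeled segment {iv.chrom}:{iv.start}-{iv.end}")
            if prev is not None and prev.chrom == iv.chrom and iv.start < prev.end:
                raise ValueError(
                    f"overlapping segments {prev.chrom}:{prev.start}-{prev.end} and "
                    f"{iv.chrom}:{iv.start}-{iv.end}")
            prev = iv
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        self._labels: dict[str, list[str]] = {}
        for iv in self.intervals:
            self._starts.setdefault(iv.chrom, []).append(iv.start)
            self._ends.setdefault(iv.chrom, []).append(iv.end)
            self._labels.setdefault(iv.chrom, []).append(iv.name)

    @property
    def total_bp(self) -> int:
        return sum(self.state_bp.values())

    def state_fractions(self) -> dict[str, float]:
        total = self.total_bp
        return {s: self.state_bp[s] / total for s in self.states}

    def overlap_by_state(self, chrom: str, start: int, end: int) -> dict[str, int]:
        """bp of [start, end) falling in each state."""
        out: dict[str, int] = {}
        if chrom not in self._starts:
            return out
        starts, ends, labels = self._starts[chrom], self._ends[chrom], self._labels[chrom]
        lo = bisect.bisect_right(ends, start)
        hi = bisect.bisect_left(starts, end)
        for k in range(lo, hi):
            bp = min(end, ends[k]) - max(start, starts[k])
            if bp > 0:
                out[labels[k]] = out.get(labels[k], 0) + bp
        return out

    def to_bed(self, path: str | Path) -> None:
        write_bed(self.intervals, path)


def read_segmentation(path: str | Path) -> Segmentation:
    """Read a BED4 segmentation; overlapping segments are an error."""
    ivs = read_bed(path).intervals
    for iv in ivs:
        if iv.name is None:
            raise BedParseError(f"{path}: segment {iv.chrom}:{iv.start}-{iv.end} "
                                "lacks a state label (BED4 required)")
    return segmentation_from_intervals(ivs)


def segmentation_from_intervals(intervals: list[Interval]) -> Segmentation:
    state_bp: dict[str, int] = {}
    for iv in intervals:
        state_bp[iv.name] = state_bp.get(iv.name, 0) + iv.length
    states = sorted(state_bp)
    return Segmentation(list(intervals), states, state_bp)


def assign_majority_state(sites: IntervalSet, seg: Segmentation) -> list[str]:
    """Per-site state covering the largest share of its bp.

    Ties break to the lexicographically smallest state label; a site with no
    segmented bp gets ``"unsegmented"``.
    """
    labels = []
    for iv in sites:
        by_state = seg.overlap_by_state(iv.chrom, iv.start, iv.end)
        if not by_state:
            labels.append("unsegmented")
        else:
            labels.append(min(by_state, key=lambda s: (-by_state[s], s)))
    return labels


def state_fraction_table(
    sites: IntervalSet,
    seg: Segmentation,
    classes: list[str] | None = None,
) -> pd.DataFrame:
    """Fraction of sites assigned to each state, optionally per subset class."""
    assigned = assign_majority_state(sites, seg)
    df = pd.DataFrame({"state": assigned,
                       "class": classes if classes is not None else ["all"] * len(assigned)})
    out = (df.groupby(["class", "state"]).size().rename("n").reset_index())
    totals = out.groupby("class")["n"].transform("sum")
    out["fraction"] = out["n"] / totals
    return out


@dataclass
class EnrichmentMatrix:
    """Observed/expected state overlap per feature set, Z-scored across states.

    ``observed``/``ratio``/``z`` are DataFrames with feature rows and state
    columns; ``expected`` the per-state genome fraction; ``flags`` marks
    feature rows with no segmented bp (ratios undefined).
    """

    observed: pd.DataFrame
    expected: pd.Series
    ratio: pd.DataFrame
    z: pd.DataFrame
    flags: dict[str, str]

    def to_tsv(self, path: str | Path) -> None:
        long = self.ratio.stack().rename("ratio").to_frame()
        long["observed"] = self.observed.stack()
        long["z"] = self.z.stack()
        long.index.names = ["feature", "state"]
        long.reset_index().to_csv(path, sep="\t", index=False, lineterminator="\n")


def state_enrichment(
    seg: Segmentation,
    features: Mapping[str, IntervalSet],
) -> EnrichmentMatrix:
    """bp-weighted state overlap enrichment with per-row Z-conversion.

    observed_k = feature bp in state k / total feature bp; expected_k =
    state-k bp / segmented bp; ratio = observed/expected; per feature row
    Z_k = (ratio_k − mean(ratio)) / sample SD(ratio).  With fewer than two
    distinct ratios the Z row is undefined (NaN) and flagged.
    """
    if not features:
        raise ValueError("no feature sets given")
    states = seg.states
    expected = pd.Series(seg.state_fractions(), index=states, name="expected")

    observed_rows, flags = {}, {}
    for name, fs in features.items():
        collapsed = fs.collapse()
        total_bp = sum(iv.length for iv in collapsed.intervals)
        by_state = dict.fromkeys(states, 0)
        for iv in collapsed.intervals:
            for state, bp in seg.overlap_by_state(iv.chrom, iv.start, iv.end).items():
                by_state[state] += bp
        if total_bp == 0 or sum(by_state.values()) == 0:
            flags[name] = "no segmented bp"
            observed_rows[name] = pd.Series(np.nan, index=states)
        else:
            observed_rows[name] = pd.Series(
                {s: by_state[s] / total_bp for s in states})
    observed = pd.DataFrame(observed_rows).T[states]

    ratio = observed.divide(expected, axis=1)
    z = pd.DataFrame(index=ratio.index, columns=states, dtype=float)
    for name, row in ratio.iterrows():
        vals = row.to_numpy(dtype=float)
        if np.isnan(vals).any() or len(set(vals)) < 2:
            if name not in flags:
                flags[name] = "Z undefined (fewer than 2 distinct ratios)"
            z.loc[name] = np.nan
        else:
            z.loc[name] = (vals - vals.mean()) / vals.std(ddof=1)
    return EnrichmentMatrix(observed, expected, ratio, z, flags)
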