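"""Random-interval background model and empirical τ calibration.

Shuffling follows the behaviour of ``bedtools shuffle -chrom``: every input
interval is re-placed uniformly at random on its own chromosome with its
length preserved.  Shuffled intervals may overlap one another within a set;
like real inputs they are collapsed before voting.

:func:`calibrate_tau` contrasts the observed consensus counts at each τ with
the counts obtained on shuffled inputs, the empirical null used to pick a
reproducibility threshold: the τ where the random count collapses while the
observed count remains high separates reproducible sites from coincidental
pile-ups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenomeLayout, Interval, IntervalSet
from .consensus import refgen


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    # documented counter scheme: each replicate is independently reproducible
    return np.random.default_rng([seed, replicate])


def shuffle_intervals(
    intervals: IntervalSet,
    layout: GenomeLayout,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    same_chrom: bool = True,
    exclude: IntervalSet | None = None,
    max_attempts: int = 1000,
) -> IntervalSet:
    """Re-place every interval uniformly at random, preserving its length.

    With ``same_chrom`` (default, mirroring ``shuffle -chrom``) each interval
    stays on its chromosome; otherwise a chromosome is drawn with probability
    proportional to the number of valid start positions.  ``exclude`` regions
    are avoided by rejection sampling (``max_attempts`` per interval).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    lengths = layout.lengths
    names = layout.names
    out: list[Interval] = []
    excl = exclude.collapse() if exclude is not None else None

    for iv in intervals:
        L = iv.length
        if same_chrom:
            chrom_len = lengths[iv.chrom]
            if L > chrom_len:
                raise ValueError(
                    f"interval of length {L} exceeds chromosome {iv.chrom} ({chrom_len} bp)")
        else:
            slots = np.array([max(0, lengths[c] - L + 1) for c in names], dtype=float)
            if slots.sum() == 0:
                raise ValueError(f"interval of length {L} fits no chromosome")
        placed = False
        for _ in range(max_attempts):
            if same_chrom:
                chrom = iv.chrom
                chrom_len = lengths[chrom]
            else:
                chrom = names[rng.choice(len(names), p=slots / slots.sum())]
                chrom_len = lengths[chrom]
            start = int(rng.integers(0, chrom_len - L + 1))
            cand = Interval(chrom, start, start + L)
            if excl is None or excl.overlap_bp_with(chrom, start, start + L) == 0:
                out.append(cand)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place a length-{L} interval outside excluded regions "
                f"after {max_attempts} attempts")
    res = IntervalSet(out, label=f"{intervals.label}.shuffled", context=intervals.context)
    return res


@dataclass
class CalibrationTable:
    """Observed vs random consensus counts per τ.

    ``table`` columns: tau, observed_n, observed_bp, rand_mean_n, rand_sd_n,
    rand_q05, rand_q95, rand_mean_bp, enrichment (observed / random mean,
    inf where the random mean is 0 and the observed count is positive).
    ``random_counts[r, t]`` holds replicate r's interval count at tau_grid[t].
    """

    table: pd.DataFrame
    random_counts: np.ndarray
    random_bp: np.ndarray
    tau_grid: list[int]
    n_reps: int
    seed: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def calibrate_tau(
    sets: Sequence[IntervalSet],
    layout: GenomeLayout,
    *,
    n_reps: int = 1000,
    seed: int = 0,
    tau_grid: Sequence[int] | None = None,
    same_chrom: bool = True,
) -> CalibrationTable:
    """Empirical random-background calibration of the consensus threshold.

    For each of ``n_reps`` replicates every input set is shuffled (same
    interval count, same lengths, same chromosomes) and the consensus is
    rebuilt at every τ in ``tau_grid`` (default 1..n_inputs); the counts of
    consensus regions (and bp) form the random null against which the
    observed counts are compared.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n = len(sets)
    if tau_grid is None:
        tau_grid = list(range(1, n + 1))
    tau_grid = [int(t) for t in tau_grid]

    observed_n, observed_bp = [], []
    for tau in tau_grid:
        res = refgen(sets, tau, layout=layout)
        observed_n.append(len(res))
        observed_bp.append(res.total_bp())

    random_counts = np.zeros((n_reps, len(tau_grid)), dtype=int)
    random_bp = np.zeros((n_reps, len(tau_grid)), dtype=int)
    for rep in range(n_reps):
        rng = _replicate_rng(seed, rep)
        shuffled = [shuffle_intervals(s, layout, rng=rng, same_chrom=same_chrom)
                    for s in sets]
        for t, tau in enumerate(tau_grid):
            res = refgen(shuffled, tau, layout=layout)
            random_counts[rep, t] = len(res)
            random_bp[rep, t] = res.total_bp()

    rand_mean = random_counts.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        enrichment = np.where(
            rand_mean > 0, np.asarray(observed_n) / rand_mean,
            np.where(np.asarray(observed_n) > 0, np.inf, np.nan))
    table = pd.DataFrame({
        "tau": tau_grid,
        "observed_n": observed_n,
        "observed_bp": observed_bp,
        "rand_mean_n": rand_mean,
        "rand_sd_n": random_counts.std(axis=0, ddof=1) if n_reps > 1 else np.zeros(len(tau_grid)),
        "rand_q05": np.quantile(random_counts, 0.05, axis=0),
        "rand_q95": np.quantile(random_counts, 0.95, axis=0),
        "rand_mean_bp": random_bp.mean(axis=0),
        "enrichment": enrichment,
    })
    return CalibrationTable(table, random_counts, random_bp, tau_grid, n_reps, seed)
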