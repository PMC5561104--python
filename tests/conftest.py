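"""Shared fixtures and independent per-base oracles.

The bitmap oracle realises interval votes literally: one boolean array per
chromosome per input set, summed into a per-base depth vector.  It is the
ground truth against which the sweep-based coverage/consensus code is
checked on toy chromosomes.
"""

from __future__ import annotations

import numpy as np
import pytest

from cistromekit import GenomeLayout, Interval, IntervalSet


@pytest.fixture
def toy_layout() -> GenomeLayout:
    return GenomeLayout.from_dict({"chr1": 100_000, "chr2": 80_000, "chr3": 50_000})


def bitmap_depth(sets, layout: GenomeLayout) -> dict[str, np.ndarray]:
    """Per-base vote depth: number of input sets covering each position."""
    depth = {c: np.zeros(n, dtype=np.int32) for c, n in layout.chromosomes}
    for s in sets:
        mask = {c: np.zeros(n, dtype=bool) for c, n in layout.chromosomes}
        for iv in s:
            mask[iv.chrom][iv.start:iv.end] = True
        for c in depth:
            depth[c] += mask[c]
    return depth


def mask_to_intervals(mask: np.ndarray, chrom: str) -> list[tuple[str, int, int]]:
    """Maximal runs of True positions as (chrom, start, end) triples."""
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(chrom, int(a), int(b)) for a, b in zip(starts, ends)]


def bitmap_refgen(sets, tau: int, layout: GenomeLayout) -> list[tuple[str, int, int]]:
    """Independent consensus: per-base vote then thresholded runs."""
    out = []
    depth = bitmap_depth(sets, layout)
    for chrom, _ in layout.chromosomes:
        out.extend(mask_to_intervals(depth[chrom] >= tau, chrom))
    return out


def random_instance(rng: np.random.Generator, layout: GenomeLayout,
                    max_sets: int = 8, max_intervals: int = 40,
                    max_len: int = 2000) -> list[IntervalSet]:
    """A random multi-set voting instance on the toy genome."""
    n_sets = int(rng.integers(1, max_sets + 1))
    sets = []
    for s in range(n_sets):
        n_iv = int(rng.integers(1, max_intervals + 1))
        ivs = []
        for _ in range(n_iv):
            chrom, clen = layout.chromosomes[int(rng.integers(0, len(layout)))]
            length = int(rng.integers(1, max_len + 1))
            start = int(rng.integers(0, clen - length + 1))
            ivs.append(Interval(chrom, start, start + length))
        sets.append(IntervalSet(ivs, label=f"set_{s}"))
    return sets
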