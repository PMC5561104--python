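"""Synthetic multi-study fixtures with planted, recoverable structure.

Every stage of the toolkit is testable without downloads: a truth cistrome
is planted on a toy genome; studies re-detect each truth site independently
with a set sensitivity, jitter its boundaries and add noise peaks (emulating
heterogeneous peak callers and sequencing depths); signal matrices carry a
shared per-site bump scaled by planted per-experiment size factors with
Poisson counting noise (emulating library-size differences and cofactor
co-binding); segmentations tile the genome with labeled state blocks and
feature sets are drawn preferentially from a planted state.

Defaults define the study conditions used throughout the test-bench: a
3 × 1 Mb genome (large enough that same-length random intervals virtually
never stack to full depth, small enough for per-base oracles), 8 studies at
sensitivity 0.9, 500 planted sites of 200–400 bp, 100 noise peaks and 20 bp
boundary jitter per study; signal over 200 bins × 50 sites with planted
size factors (1.0, 2.5, 0.4) and a baseline Poisson mean of 15, so that
every scaled mean stays at or above 5 and the count matrix has essentially
no zero bins.

Everything is deterministic given (spec, seed); peak provenance
(``true_<i>`` / ``noise_<k>``) is recorded in the BED name field.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenomeLayout, Interval, IntervalSet, write_bed
from .signal import BinCountMatrix, BinScheme
from .states import Segmentation, segmentation_from_intervals


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the planted-structure generator (see module docstring)."""

    seed: int = 0
    # genome
    n_chroms: int = 3
    chrom_length: int = 1_000_000
    # truth cistrome
    n_sites: int = 500
    site_len_min: int = 200
    site_len_max: int = 400
    # studies
    n_studies: int = 8
    sensitivity: float = 0.9
    noise_peaks: int = 100
    jitter_sd: float = 20.0
    # signal
    size_factors: tuple[float, ...] = (1.0, 2.5, 0.4)
    bump_amplitude: float = 20.0
    bump_sd_bins: float = 8.0
    baseline: float = 15.0
    # segmentation
    states: tuple[str, ...] = ("S1", "S2", "S3", "S4", "S5")
    block_size: int = 1000
    planted_state: str = "S1"
    planted_prob: float = 0.8
    n_features: int = 300
    feature_len: int = 200

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0):
            raise ValueError("sensitivity must be in [0, 1]")
        if self.site_len_min <= 0 or self.site_len_max < self.site_len_min:
            raise ValueError("invalid site length range")
        if any(s <= 0 for s in self.size_factors):
            raise ValueError("planted size factors must be strictly positive")
        if self.planted_state not in self.states:
            raise ValueError("planted_state must be in the state catalog")

    def layout(self) -> GenomeLayout:
        return GenomeLayout.from_dict(
            {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)})


def simulate_truth(spec: SimulationSpec,
                   rng: np.random.Generator | None = None) -> IntervalSet:
    """Non-overlapping truth cistrome, uniform placement by rejection sampling."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    layout = spec.layout()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.names}
    out: list[Interval] = []
    for i in range(spec.n_sites):
        for attempt in range(1000):
            chrom = layout.names[int(rng.integers(0, len(layout)))]
            length = int(rng.integers(spec.site_len_min, spec.site_len_max + 1))
            start = int(rng.integers(0, layout.length_of(chrom) - length + 1))
            end = start + length
            if all(end <= s or start >= e for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                out.append(Interval(chrom, start, end, name=f"true_{i + 1}"))
                break
        else:
            raise RuntimeError(
                f"could not place site {i + 1}/{spec.n_sites} without overlap; "
                "use a larger genome or fewer/shorter sites")
    out.sort(key=lambda iv: (iv.chrom, iv.start))
    return IntervalSet(out, label="truth")


def simulate_studies(
    truth: IntervalSet,
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
) -> list[IntervalSet]:
    """Per-study peak sets: truth sites detected with probability
    ``sensitivity`` (boundaries jittered), plus uniform noise peaks."""
    rng = rng if rng is not None else np.random.default_rng([spec.seed, 1])
    layout = spec.layout()
    studies: list[IntervalSet] = []
    for s in range(spec.n_studies):
        peaks: list[Interval] = []
        for iv in truth:
            if rng.random() >= spec.sensitivity:
                continue
            ds = int(round(rng.normal(0.0, spec.jitter_sd)))
            de = int(round(rng.normal(0.0, spec.jitter_sd)))
            start = max(0, iv.start + ds)
            end = min(layout.length_of(iv.chrom), iv.end + de)
            if end <= start:                       # jitter collapsed the peak
                center = iv.center
                start, end = max(0, center - 1), center + 1
            peaks.append(Interval(iv.chrom, start, end, name=iv.name))
        for k in range(spec.noise_peaks):
            chrom = layout.names[int(rng.integers(0, len(layout)))]
            length = int(rng.integers(spec.site_len_min, spec.site_len_max + 1))
            start = int(rng.integers(0, layout.length_of(chrom) - length + 1))
            peaks.append(Interval(chrom, start, start + length, name=f"noise_{k + 1}"))
        peaks.sort(key=lambda iv: (iv.chrom, iv.start))
        studies.append(IntervalSet(peaks, label=f"study_{s + 1}"))
    return studies


def simulate_signal(
    sites: IntervalSet,
    spec: SimulationSpec,
    *,
    scheme: BinScheme = BinScheme(),
    labels: Sequence[str] | None = None,
    shared_bump: Sequence[bool] | None = None,
    col_meta: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> BinCountMatrix:
    """Binned count matrix with a planted shared bump and planted size factors.

    Experiment i's mean in bin b of site j is ``s*_i · (baseline + A_j ·
    exp(−(b − c)² / 2σ²))`` when experiment i shares the bump (cofactor-like)
    and ``s*_i · baseline`` when it does not (independent/null factor);
    counts are Poisson.  Per-site amplitudes A_j vary ±50% around
    ``bump_amplitude`` so sites are not interchangeable.
    """
    rng = rng if rng is not None else np.random.default_rng([spec.seed, 2])
    s_star = np.asarray(spec.size_factors, dtype=float)
    n_exp = len(s_star)
    if shared_bump is None:
        shared_bump = [True] * n_exp
    if len(shared_bump) != n_exp:
        raise ValueError("shared_bump length must match size_factors")
    if labels is None:
        labels = [f"exp_{i + 1}" for i in range(n_exp)]

    n_bins = scheme.n_bins
    site_ids = [iv.name or f"site_{j + 1}" for j, iv in enumerate(sites)]
    bins = np.arange(n_bins)
    center = (n_bins - 1) / 2.0
    bump_shape = np.exp(-((bins - center) ** 2) / (2.0 * spec.bump_sd_bins ** 2))
    amplitudes = spec.bump_amplitude * rng.uniform(0.5, 1.5, size=len(site_ids))

    values = np.zeros((len(site_ids) * n_bins, n_exp))
    for j, amp in enumerate(amplitudes):
        site_mean = spec.baseline + amp * bump_shape
        for i in range(n_exp):
            mean = (site_mean if shared_bump[i] else np.full(n_bins, spec.baseline))
            values[j * n_bins:(j + 1) * n_bins, i] = rng.poisson(s_star[i] * mean)

    row_meta = pd.DataFrame({
        "site_id": np.repeat(site_ids, n_bins),
        "bin_index": np.tile(bins, len(site_ids)),
    })
    if col_meta is None:
        col_meta = pd.DataFrame({"label": list(labels),
                                 "factor": list(labels),
                                 "context": [""] * n_exp})
    return BinCountMatrix(values, row_meta, col_meta.reset_index(drop=True))


def simulate_segmentation(
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
) -> tuple[Segmentation, IntervalSet]:
    """Genome tiled by cycling state blocks, plus a feature set drawn from the
    planted state with probability ``planted_prob`` (uniform elsewhere)."""
    rng = rng if rng is not None else np.random.default_rng([spec.seed, 3])
    layout = spec.layout()
    segs: list[Interval] = []
    planted_blocks: list[Interval] = []
    k = 0
    for chrom, length in layout.chromosomes:
        for start in range(0, length, spec.block_size):
            end = min(start + spec.block_size, length)
            state = spec.states[k % len(spec.states)]
            seg = Interval(chrom, start, end, name=state)
            segs.append(seg)
            if state == spec.planted_state:
                planted_blocks.append(seg)
            k += 1
    seg = segmentation_from_intervals(segs)

    features: list[Interval] = []
    for i in range(spec.n_features):
        if rng.random() < spec.planted_prob:
            block = planted_blocks[int(rng.integers(0, len(planted_blocks)))]
            hi = max(block.start + 1, block.end - spec.feature_len)
            start = int(rng.integers(block.start, hi))
            end = min(start + spec.feature_len, block.end)
        else:
            chrom = layout.names[int(rng.integers(0, len(layout)))]
            start = int(rng.integers(0, layout.length_of(chrom) - spec.feature_len))
            end = start + spec.feature_len
            features.append(Interval(chrom, start, end, name=f"feat_{i + 1}"))
            continue
        features.append(Interval(block.chrom, start, end, name=f"feat_{i + 1}"))
    features.sort(key=lambda iv: (iv.chrom, iv.start))
    return seg, IntervalSet(features, label="features")


def write_fixtures(spec: SimulationSpec, outdir: str | Path) -> dict:
    """Write a full fixture bundle (BEDs, matrix TSV, segmentation, manifest).

    Returns the manifest dict; all files validate through the package's own
    readers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = spec.layout()
    layout.to_file(outdir / "genome.chrom.sizes")

    truth = simulate_truth(spec)
    write_bed(truth, outdir / "truth.bed")
    studies = simulate_studies(truth, spec)
    study_files = []
    for s in studies:
        path = outdir / f"{s.label}.bed"
        write_bed(s, path)
        study_files.append(path.name)

    signal_sites = IntervalSet(truth.intervals[:50], label="signal_sites")
    write_bed(signal_sites, outdir / "signal_sites.bed")
    matrix = simulate_signal(signal_sites, spec)
    matrix.to_tsv(outdir / "counts.tsv")

    seg, features = simulate_segmentation(spec)
    seg.to_bed(outdir / "segmentation.bed")
    write_bed(features, outdir / "features.bed")

    manifest = {
        "schema_version": 1,
        "generator": "cistromekit.simulate",
        "spec": asdict(spec),
        "files": {
            "genome": "genome.chrom.sizes",
            "truth": "truth.bed",
            "studies": study_files,
            "signal_sites": "signal_sites.bed",
            "counts": "counts.tsv",
            "segmentation": "segmentation.bed",
            "features": "features.bed",
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
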