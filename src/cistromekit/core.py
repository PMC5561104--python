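"""Genomic interval model, BED / chrom.sizes I/O, coverage and set operations.

Coordinates are BED-style 0-based half-open everywhere inside the package;
1-based inclusive inputs (common in publication supplementary tables) are
converted at the reading boundary via ``one_based=True``.  Strand is ignored
throughout: every analysis here is strand-symmetric.

A :class:`GenomeLayout` is the coordinate authority.  When one is attached,
intervals must fit inside their chromosome (``clip=True`` truncates instead
of erroring) and records on unknown chromosomes are rejected or dropped.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence


class BedParseError(ValueError):
    """A malformed BED record (non-integer coordinates, inverted span, ...)."""


class LayoutError(ValueError):
    """An interval incompatible with the attached genome layout."""


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names with lengths (UCSC chrom.sizes semantics).

    Input order is preserved; it fixes the sort order of every output that
    spans chromosomes.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @classmethod
    def from_dict(cls, sizes: Mapping[str, int]) -> "GenomeLayout":
        return cls(tuple((str(k), int(v)) for k, v in sizes.items()))

    @classmethod
    def from_file(cls, path: str | Path) -> "GenomeLayout":
        """Read a two-column ``name<TAB>length`` chrom.sizes file."""
        chroms: list[tuple[str, int]] = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise BedParseError(f"{path}:{lineno}: expected 'name<TAB>length'")
                try:
                    length = int(fields[1])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from exc
                chroms.append((fields[0], length))
        return cls(tuple(chroms))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __len__(self) -> int:
        return len(self.chromosomes)

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise LayoutError(f"chromosome {chrom!r} not in layout") from None

    def sort_key(self, chrom: str) -> tuple[int, str]:
        """Sort key honouring layout order; unknown chromosomes go last, lexicographically."""
        try:
            return (self.names.index(chrom), chrom)
        except ValueError:
            return (len(self.names), chrom)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chromosomes:
                fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end}) on {self.chrom}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, floor((start+end)/2) — the anchor for signal windows."""
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class IntervalSet:
    """A named collection of intervals: one peak set / cistrome.

    ``collapse()`` returns the minimal sorted, pairwise non-overlapping set
    with the same genomic union; a set must be collapsed before it is used to
    vote (one dataset contributes at most one vote per position).
    """

    def __init__(
        self,
        intervals: Iterable[Interval] = (),
        label: str = "",
        context: str | None = None,
        *,
        collapsed: bool = False,
    ) -> None:
        self.intervals: list[Interval] = list(intervals)
        self.label = label
        self.context = context
        self._collapsed = collapsed
        self._index: dict[str, tuple[list[int], list[int]]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __repr__(self) -> str:
        return f"IntervalSet({self.label!r}, n={len(self)})"

    @property
    def is_collapsed(self) -> bool:
        return self._collapsed

    def chrom_names(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}

    def total_bp(self) -> int:
        """bp of the genomic union (collapses first)."""
        return sum(iv.length for iv in self.collapse().intervals)

    def sorted(self, layout: GenomeLayout | None = None) -> "IntervalSet":
        key = (lambda iv: (layout.sort_key(iv.chrom), iv.start, iv.end)) if layout else (
            lambda iv: (iv.chrom, iv.start, iv.end))
        out = IntervalSet(sorted(self.intervals, key=key), self.label, self.context)
        out._collapsed = self._collapsed
        return out

    def collapse(self, layout: GenomeLayout | None = None) -> "IntervalSet":
        """Merge overlapping and book-ended intervals; idempotent."""
        if self._collapsed:
            return self
        merged: list[Interval] = []
        for iv in self.sorted(layout).intervals:
            if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
                if iv.end > merged[-1].end:
                    merged[-1] = replace(merged[-1], end=iv.end, name=None, score=None)
            else:
                merged.append(replace(iv, name=None, score=None) if (iv.name or iv.score is not None) else iv)
        return IntervalSet(merged, self.label, self.context, collapsed=True)

    def _chrom_index(self) -> dict[str, tuple[list[int], list[int]]]:
        # collapsed per-chromosome (starts, ends) arrays for bisect overlap queries
        if self._index is None:
            idx: dict[str, tuple[list[int], list[int]]] = {}
            for iv in self.collapse().intervals:
                starts, ends = idx.setdefault(iv.chrom, ([], []))
                starts.append(iv.start)
                ends.append(iv.end)
            self._index = idx
        return self._index

    def overlap_bp_with(self, chrom: str, start: int, end: int) -> int:
        """bp of ``[start, end)`` covered by this set's union."""
        idx = self._chrom_index()
        if chrom not in idx:
            return 0
        starts, ends = idx[chrom]
        lo = bisect.bisect_right(ends, start)
        hi = bisect.bisect_left(starts, end)
        return sum(min(end, ends[k]) - max(start, starts[k]) for k in range(lo, hi))

    def overlaps(self, chrom: str, start: int, end: int, min_bp: int = 1) -> bool:
        return self.overlap_bp_with(chrom, start, end) >= min_bp

    def validate(self, layout: GenomeLayout, clip: bool = False) -> "IntervalSet":
        """Check every interval against the layout; ``clip`` truncates overhangs."""
        out: list[Interval] = []
        for iv in self.intervals:
            length = layout.length_of(iv.chrom)
            if iv.end > length:
                if not clip:
                    raise LayoutError(
                        f"{iv.chrom}:{iv.start}-{iv.end} exceeds chromosome length {length}")
                if iv.start >= length:
                    continue
                iv = replace(iv, end=length)
            out.append(iv)
        res = IntervalSet(out, self.label, self.context)
        res._collapsed = self._collapsed and len(out) == len(self.intervals)
        return res

    def drop_chroms(self, chroms: Iterable[str]) -> "IntervalSet":
        drop = set(chroms)
        out = IntervalSet([iv for iv in self.intervals if iv.chrom not in drop],
                          self.label, self.context)
        out._collapsed = self._collapsed
        return out


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def read_bed(
    path: str | Path,
    layout: GenomeLayout | None = None,
    *,
    one_based: bool = False,
    on_unknown_chrom: str = "error",
    drop_chroms: Iterable[str] = (),
    clip: bool = False,
    label: str | None = None,
    context: str | None = None,
) -> IntervalSet:
    """Read a BED3+ file into an :class:`IntervalSet`.

    Parameters
    ----------
    one_based
        Treat input starts as 1-based inclusive and convert.
    on_unknown_chrom
        ``"error"`` or ``"drop"`` for records on chromosomes absent from
        *layout* (ignored when no layout is given).
    clip
        Truncate intervals overhanging chromosome ends instead of erroring.
    """
    if on_unknown_chrom not in ("error", "drop"):
        raise ValueError("on_unknown_chrom must be 'error' or 'drop'")
    path = Path(path)
    drop = set(drop_chroms)
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or any(line.startswith(p) for p in _SKIP_PREFIXES):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if one_based:
                start -= 1
            if start < 0 or start >= end:
                raise BedParseError(f"{path}:{lineno}: invalid span [{start}, {end})")
            if chrom in drop:
                continue
            if layout is not None and chrom not in layout:
                if on_unknown_chrom == "drop":
                    continue
                raise BedParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None  # tolerate non-numeric score column
            intervals.append(Interval(chrom, start, end, name, score))
    if not intervals:
        warnings.warn(f"{path}: no intervals parsed", stacklevel=2)
    out = IntervalSet(intervals, label=label if label is not None else path.stem,
                      context=context)
    if layout is not None:
        out = out.validate(layout, clip=clip)
    return out


def _format_score(score: float) -> str:
    if float(score).is_integer():
        return str(int(score))
    return repr(float(score))


def write_bed(intervals: "IntervalSet | Iterable[Interval]", path: str | Path) -> None:
    """Write intervals as BED (3, 4 or 5 columns as populated), LF-terminated."""
    if isinstance(intervals, IntervalSet):
        intervals = intervals.intervals
    with open(path, "w", newline="\n") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                cols.append(_format_score(iv.score))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageTrack:
    """Per-chromosome step function of vote depth.

    ``segments[chrom]`` is a sorted list of ``(start, end, depth)`` with
    depth ≥ 1; positions not covered by any segment have depth 0.
    """

    segments: dict[str, list[tuple[int, int, int]]]
    n_inputs: int

    def depth_at(self, chrom: str, pos: int) -> int:
        for start, end, depth in self.segments.get(chrom, []):
            if start <= pos < end:
                return depth
            if start > pos:
                break
        return 0

    def bp_at_depth(self, min_depth: int = 1) -> int:
        return sum(end - start
                   for segs in self.segments.values()
                   for start, end, depth in segs
                   if depth >= min_depth)

    def depth_histogram(self) -> dict[int, int]:
        """bp covered at each exact depth ≥ 1."""
        hist: dict[int, int] = {}
        for segs in self.segments.values():
            for start, end, depth in segs:
                hist[depth] = hist.get(depth, 0) + (end - start)
        return hist


def coverage(
    sets: Sequence[IntervalSet],
    layout: GenomeLayout | None = None,
    *,
    permissive: bool = False,
) -> CoverageTrack:
    """Vote-depth coverage: depth at p = number of input sets covering p.

    Each input set is collapsed first, so a set contributes at most one vote
    per position.  Without a layout, a differing chromosome universe across
    sets is an error unless ``permissive``; a layout defines the universe and
    silences the check.
    """
    if not sets:
        raise ValueError("coverage requires at least one input set")
    collapsed = [s.collapse() for s in sets]
    if layout is None and not permissive and len(collapsed) > 1:
        universes = [s.chrom_names() for s in collapsed if len(s)]
        if universes and any(u != universes[0] for u in universes[1:]):
            raise ValueError(
                "input sets cover different chromosome universes; "
                "pass a GenomeLayout or permissive=True")
    if layout is not None:
        for s in collapsed:
            for chrom in s.chrom_names():
                if chrom not in layout:
                    raise LayoutError(f"set {s.label!r}: chromosome {chrom!r} not in layout")

    events: dict[str, list[tuple[int, int]]] = {}
    for s in collapsed:
        for iv in s.intervals:
            ev = events.setdefault(iv.chrom, [])
            ev.append((iv.start, 1))
            ev.append((iv.end, -1))

    segments: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, ev in events.items():
        ev.sort()
        segs: list[tuple[int, int, int]] = []
        depth = 0
        prev = None
        for pos, delta in ev:
            if prev is not None and pos > prev and depth > 0:
                if segs and segs[-1][1] == prev and segs[-1][2] == depth:
                    segs[-1] = (segs[-1][0], pos, depth)
                else:
                    segs.append((prev, pos, depth))
            depth += delta
            prev = pos
        segments[chrom] = segs

    chrom_order = (lambda c: layout.sort_key(c)) if layout else (lambda c: c)
    return CoverageTrack({c: segments[c] for c in sorted(segments, key=chrom_order)},
                         n_inputs=len(sets))
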