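"""Majority-vote consensus cistrome construction and downstream classing.

The central operation, :func:`refgen`, turns a collection of peak sets into a
consensus cistrome: every input set is collapsed (one vote per dataset per
position), a vote-depth coverage is computed, and maximal runs of positions
with depth ≥ τ become consensus intervals.  τ = 1 yields the collapsed union,
τ = n the per-base intersection; any value in between is a reproducibility
("severity") threshold.

:func:`build_reference` chains three refgen passes the way multi-study
integrations are organised in practice: within a study all replicates must
agree (τ = number of replicates); within an experimental context a fraction
of the studies must agree (default 75%, rounded up); the final reference is
the union over contexts (τ = 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core import CoverageTrack, GenomeLayout, Interval, IntervalSet, coverage, write_bed


@dataclass
class ConsensusResult:
    """Consensus intervals with per-interval support (max vote depth in the run)."""

    intervals: list[Interval]          # score field carries the support
    supports: list[int]
    tau: int
    n_inputs: int
    input_labels: list[str]
    label: str = "consensus"

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.supports):
            raise ValueError("intervals and supports length mismatch")
        for s in self.supports:
            if not (self.tau <= s <= self.n_inputs):
                raise ValueError(f"support {s} outside [tau={self.tau}, n={self.n_inputs}]")

    def __len__(self) -> int:
        return len(self.intervals)

    def total_bp(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def to_interval_set(self, label: str | None = None, context: str | None = None) -> IntervalSet:
        out = IntervalSet(self.intervals, label=label or self.label, context=context)
        out._collapsed = True  # maximal runs are sorted and disjoint by construction
        return out

    def to_bed(self, path) -> None:
        """BED5 with ``consensus_<i>`` names and support in the score column."""
        named = [
            Interval(iv.chrom, iv.start, iv.end, f"consensus_{i + 1}", float(sup))
            for i, (iv, sup) in enumerate(zip(self.intervals, self.supports))
        ]
        write_bed(named, path)


def effective_tau(tau: float, n_inputs: int, mode: str = "count") -> int:
    """Resolve a τ parameter: a count, or a fraction of inputs rounded up."""
    if mode == "fraction":
        if not (0 < tau <= 1):
            raise ValueError(f"fractional tau must be in (0, 1], got {tau}")
        eff = math.ceil(tau * n_inputs)
    elif mode == "count":
        eff = int(tau)
        if eff != tau:
            raise ValueError(f"tau in count mode must be an integer, got {tau}")
    else:
        raise ValueError(f"unknown tau mode {mode!r}")
    if not (1 <= eff <= n_inputs):
        raise ValueError(f"tau={eff} outside [1, {n_inputs}]")
    return eff


def refgen(
    sets: Sequence[IntervalSet],
    tau: float,
    *,
    tau_mode: str = "count",
    min_len: int = 1,
    layout: GenomeLayout | None = None,
    permissive: bool = True,
    label: str = "consensus",
) -> ConsensusResult:
    """Majority-vote consensus over peak sets.

    Returns the maximal runs of genomic positions covered by at least τ of
    the (collapsed) input sets.  Support per output interval is the maximum
    vote depth reached inside the run.
    """
    if not sets:
        raise ValueError("refgen requires at least one input set")
    n = len(sets)
    eff_tau = effective_tau(tau, n, tau_mode)
    track = coverage(sets, layout, permissive=permissive)

    intervals: list[Interval] = []
    supports: list[int] = []
    for chrom, segs in track.segments.items():
        run_start = run_end = None
        run_support = 0
        for start, end, depth in segs:
            if depth >= eff_tau:
                if run_end == start:          # contiguous qualifying segment
                    run_end = end
                    run_support = max(run_support, depth)
                else:
                    if run_start is not None:
                        intervals.append(Interval(chrom, run_start, run_end))
                        supports.append(run_support)
                    run_start, run_end, run_support = start, end, depth
            else:
                if run_start is not None:
                    intervals.append(Interval(chrom, run_start, run_end))
                    supports.append(run_support)
                    run_start = run_end = None
                    run_support = 0
        if run_start is not None:
            intervals.append(Interval(chrom, run_start, run_end))
            supports.append(run_support)

    if min_len > 1:
        kept = [(iv, s) for iv, s in zip(intervals, supports) if iv.length >= min_len]
        intervals = [iv for iv, _ in kept]
        supports = [s for _, s in kept]

    return ConsensusResult(
        intervals=intervals,
        supports=supports,
        tau=eff_tau,
        n_inputs=n,
        input_labels=[s.label for s in sets],
        label=label,
    )


# ---------------------------------------------------------------------------
# Hierarchical reference construction
# ---------------------------------------------------------------------------

@dataclass
class ReferenceBuild:
    """All cistromes produced by the replicates → studies → contexts chain."""

    study_cistromes: dict[tuple[str, str], ConsensusResult]   # (context, study)
    context_cistromes: dict[str, ConsensusResult]
    reference: ConsensusResult
    context_taus: dict[str, int] = field(default_factory=dict)


def build_reference(
    plan: Mapping[str, Mapping[str, Sequence[IntervalSet]]],
    *,
    context_tau: float = 0.75,
    context_tau_mode: str = "fraction",
    layout: GenomeLayout | None = None,
    min_len: int = 1,
) -> ReferenceBuild:
    """Three-level consensus: replicates (all), studies (fraction), contexts (any).

    ``plan`` maps context → study → replicate peak sets.  Per study every
    replicate must cover a position (τ = n_replicates); per context the
    study-level cistromes are voted with the configurable rule (default:
    ceil(0.75 · n_studies)); the reference is the τ = 1 union of the
    context cistromes.
    """
    if not plan:
        raise ValueError("empty plan")
    study_cistromes: dict[tuple[str, str], ConsensusResult] = {}
    context_cistromes: dict[str, ConsensusResult] = {}
    context_taus: dict[str, int] = {}

    for context, studies in plan.items():
        if not studies:
            raise ValueError(f"context {context!r} has no studies")
        per_study_sets: list[IntervalSet] = []
        for study, replicates in studies.items():
            if not replicates:
                raise ValueError(f"study {study!r} in context {context!r} has no replicates")
            res = refgen(list(replicates), tau=len(replicates), layout=layout,
                         label=f"{context}/{study}")
            study_cistromes[(context, study)] = res
            per_study_sets.append(res.to_interval_set(context=context))
        ctx_res = refgen(per_study_sets, tau=context_tau, tau_mode=context_tau_mode,
                         layout=layout, min_len=min_len, label=context)
        context_cistromes[context] = ctx_res
        context_taus[context] = ctx_res.tau

    reference = refgen(
        [res.to_interval_set(context=ctx) for ctx, res in context_cistromes.items()],
        tau=1, layout=layout, label="reference")
    return ReferenceBuild(study_cistromes, context_cistromes, reference, context_taus)


# ---------------------------------------------------------------------------
# Co-occurrence classing
# ---------------------------------------------------------------------------

@dataclass
class CooccurrenceClassing:
    """Partition of reference sites by the number of contexts detecting them.

    A site overlapping k context cistromes gets class ``Ck`` (C1 = context-
    specific, C<n> = constitutive across all n contexts).  ``C0`` can only
    appear for a user-supplied reference that was not built from the given
    contexts.
    """

    site_contexts: list[frozenset[str]]
    labels: list[str]
    class_counts: dict[str, int]
    contexts: list[str]

    def __len__(self) -> int:
        return len(self.labels)

    def sites_in_class(self, label: str) -> list[int]:
        return [i for i, lab in enumerate(self.labels) if lab == label]


def classify_cooccurrence(
    reference: ConsensusResult | IntervalSet,
    context_cistromes: Mapping[str, IntervalSet],
    *,
    min_overlap_bp: int = 1,
    user_supplied: bool = False,
) -> CooccurrenceClassing:
    """Class each reference site by how many context cistromes overlap it."""
    if not context_cistromes:
        raise ValueError("no context cistromes given")
    ref_set = reference.to_interval_set() if isinstance(reference, ConsensusResult) else reference
    collapsed = {ctx: cs.collapse() for ctx, cs in context_cistromes.items()}

    site_contexts: list[frozenset[str]] = []
    labels: list[str] = []
    for iv in ref_set.intervals:
        hits = frozenset(
            ctx for ctx, cs in collapsed.items()
            if cs.overlap_bp_with(iv.chrom, iv.start, iv.end) >= min_overlap_bp)
        if not hits and not user_supplied:
            raise ValueError(
                f"reference interval {iv.chrom}:{iv.start}-{iv.end} overlaps no context; "
                "a reference built as the union of these contexts cannot contain it "
                "(pass user_supplied=True to class it as C0)")
        if not hits:
            warnings.warn(f"{iv.chrom}:{iv.start}-{iv.end} overlaps no context (C0)",
                          stacklevel=2)
        site_contexts.append(hits)
        labels.append(f"C{len(hits)}")

    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    return CooccurrenceClassing(site_contexts, labels, counts, list(context_cistromes))


# ---------------------------------------------------------------------------
# Overlap annotation against independent feature sets
# ---------------------------------------------------------------------------

@dataclass
class OverlapAnnotation:
    """Replicate-supported overlap of reference sites with feature groups.

    A site is a hit for a group iff it overlaps at least ``min_support`` of
    the group's replicate sets (e.g. 2 of 3 chromatin-interaction-anchor
    replicates; all replicates for copy-number regions).
    """

    hits: dict[str, list[bool]]          # group -> per-site flags
    fractions: dict[str, float]
    min_support: dict[str, int]
    n_sites: int


def annotate_overlap(
    reference: ConsensusResult | IntervalSet,
    feature_groups: Mapping[str, Sequence[IntervalSet]],
    min_support: Mapping[str, int] | None = None,
    *,
    min_overlap_bp: int = 1,
) -> OverlapAnnotation:
    """Annotate each reference site with replicate-supported feature overlap."""
    ref_set = reference.to_interval_set() if isinstance(reference, ConsensusResult) else reference
    min_support = dict(min_support or {})
    for name in min_support:
        if name not in feature_groups:
            raise ValueError(f"min_support references unknown feature group {name!r}")
    hits: dict[str, list[bool]] = {}
    fractions: dict[str, float] = {}
    used_support: dict[str, int] = {}
    n_sites = len(ref_set)

    for name, replicates in feature_groups.items():
        support = min_support.get(name, 1)
        if replicates and support > len(replicates):
            raise ValueError(
                f"min_support[{name!r}]={support} exceeds {len(replicates)} replicate sets")
        collapsed = [r.collapse() for r in replicates]
        flags = []
        for iv in ref_set.intervals:
            n_hit = sum(
                1 for r in collapsed
                if r.overlap_bp_with(iv.chrom, iv.start, iv.end) >= min_overlap_bp)
            flags.append(bool(collapsed) and n_hit >= support)
        hits[name] = flags
        fractions[name] = (sum(flags) / n_sites) if n_sites else 0.0
        used_support[name] = support

    return OverlapAnnotation(hits, fractions, used_support, n_sites)
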