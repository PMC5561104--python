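# cistromekit

An integrative toolkit for dissecting the genomic activity of a
transcriptional regulator (TR) from heterogeneous ChIP-seq data.  Public
repositories hold dozens of peak sets and alignment files for well-studied
factors (estrogen receptor α in breast cancer cells, glucocorticoid receptor
in lung cancer cells, ...), produced with different antibodies, platforms and
depths.  cistromekit turns such collections into a single, reproducible
analysis for the bioinformatician integrating them:

1. **Reference cistrome** — a majority-vote consensus over peak sets.  Each
   input set is collapsed to one vote per genomic position; positions covered
   by at least τ of *n* inputs form the consensus.  Applied hierarchically
   (all replicates within a study → 75% of studies within an experimental
   context → union over contexts) it yields context cistromes, a reference
   cistrome, and co-occurrence classes C1…Ck (sites seen in one … all
   contexts).  The threshold is calibrated against shuffled-interval
   backgrounds (same counts, lengths and chromosomes, random placement).
2. **Cofactor co-occupancy** — read counts in 50-bp bins over ±5 kbp windows
   centred on each site are normalized with median-of-ratios size factors
   and compared by per-site Pearson correlation between the TR of interest
   and each candidate cofactor, summarised per co-occurrence class.
3. **Epigenetic classification** — a chromatin-state segmentation (consumed,
   not learned) is overlaid on the sites: majority-state assignment per site
   and bp-weighted observed/expected state enrichment, Z-scored across states.

## The statistics at the core

**Consensus vote.**  For collapsed input sets *S₁…Sₙ*, the coverage depth at
position *p* is d(p) = |{i : p ∈ Sᵢ}|; the consensus at threshold τ is the
set of maximal runs {p : d(p) ≥ τ}, with per-interval support max d.
τ = 1 gives the collapsed union, τ = n the intersection; fractional τ rounds
up (75% of 4 studies → 3).

**Size factors.**  For a count matrix M[j,i] (row j = site×bin, column i =
experiment, N experiments), with the geometric mean taken over rows whose
counts are all positive:

    G_j = (∏ᵢ M[j,i])^(1/N),      s_i = medianⱼ ( M[j,i] / G_j )

and the normalized signal is M[j,i]/s_i.  The median over bins makes s
robust to the minority of bins with genuine occupancy differences.  Applied
twice — per factor across contexts, then per context across factors — it
supports both inter-context and intra-context comparisons.

**State enrichment.**  For a feature set against states k = 1…K:
observedₖ = feature bp in state k / feature bp, expectedₖ = state-k bp /
segmented bp, ratioₖ = observedₖ/expectedₖ, and Zₖ standardizes the ratios
across states within the feature (sample SD).

## Worked example

```python
from cistromekit import Interval, IntervalSet, refgen

A = IntervalSet([Interval("chr1", 10, 30), Interval("chr1", 50, 60)], "labA")
B = IntervalSet([Interval("chr1", 20, 40)], "labB")
C = IntervalSet([Interval("chr1", 25, 35), Interval("chr1", 55, 58)], "labC")
for tau in (1, 2, 3):
    res = refgen([A, B, C], tau, permissive=True)
    print(f"tau={tau}:", [(iv.chrom, iv.start, iv.end, s)
                          for iv, s in zip(res.intervals, res.supports)])
```

prints

```
tau=1: [('chr1', 10, 40, 3), ('chr1', 50, 60, 2)]
tau=2: [('chr1', 20, 35, 3), ('chr1', 55, 58, 2)]
tau=3: [('chr1', 25, 30, 3)]
```

— at τ=1 the collapsed union of the three peak sets (support = deepest
vote inside each run), at τ=2 the majority regions, at τ=3 the triple
intersection [25,30).  Normalization on a 3-bin toy matrix:

```python
import numpy as np, pandas as pd
from cistromekit import BinCountMatrix, normchip, normchip_size_factors

m = BinCountMatrix(np.array([[2., 8], [4, 16], [6, 24]]),
                   pd.DataFrame({"site_id": ["s1"] * 3, "bin_index": [0, 1, 2]}),
                   pd.DataFrame({"label": ["expA", "expB"],
                                 "factor": ["expA", "expB"], "context": ["", ""]}))
print("size factors:", normchip_size_factors(m))
print(normchip(m).values)
```

```
size factors: [0.5 2. ]
[[ 4.  4.]
 [ 8.  8.]
 [12. 12.]]
```

expA is half as deep as the per-bin geometric mean and expB twice as deep;
dividing each column by its size factor brings both onto the common profile
(4, 8, 12).

## Command line

Every stage is a subcommand (`cistromekit refgen | classify | calibrate |
extract | normalize | correlate | annotate | enrich | state-assign |
simulate | run`); data goes to files, logs to stderr, exit codes 0/2/3 for
success / validation error / runtime error.  `cistromekit run --plan
plan.yaml` sequences the full analysis from a YAML plan (contexts → studies
→ replicate BEDs, plus optional calibration, signal, correlation, feature
and segmentation sections); re-runs are byte-identical.  `cistromekit
simulate` writes a synthetic fixture bundle with planted consensus sites,
size factors and state associations for benchmarking.

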