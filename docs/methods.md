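# Methods

This note documents the models and procedures implemented in `zurchip`, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic study does and does not demonstrate.

## The measurement model

A two-color tiling-array ChIP experiment co-hybridizes immunoprecipitated
DNA (IP, one dye) and whole-cell-extract control DNA (WCE, the other dye) to
probes at near-uniform spacing across the genome. Per probe, the quantity of
interest is the log2 ratio M = log2(IP/WCE); enrichment by a bound protein
raises M over a region whose width is set by the sonicated fragment size,
while the dyes introduce a bias that depends on overall intensity
A = (log2 IP + log2 WCE)/2.

## Normalization

`loess_correct` removes the dye bias by subtracting a robust locally
weighted degree-1 regression of M on A (statsmodels `lowess`):

- **span** (fraction of probes per local window): default **0.4**. No value
  is canonical for this design; 0.3–0.5 is standard two-color practice and
  the result is insensitive in that range for a smooth bias.
- **robustness iterations**: 3 bisquare reweightings, so enriched probes
  (large positive residuals) are effectively excluded from the fit. For this
  reason the fit is computed on *all* probes — on a genome-tiling array,
  bound regions are a small fraction of probes and masking them first is
  unnecessary.
- **delta** (fitter interpolation shortcut): 1% of the A range. Error is
  negligible for a smooth bias; the speedup on ~18k probes is large.
- Degenerate input (all A equal) falls back to subtracting the mean of M,
  with a warning.

A local linear fit reproduces any degree ≤ 1 bias exactly (residuals at
float precision); for curved biases the usual smoother bias of order
g''·h²/2 remains, which is why residual guarantees are stated away from the
extreme 5% tails of the A range, where one-sided windows inflate it.
Note the smoother is not a projection: re-correcting an already corrected
track is a no-op only when the first fit was exact (constant or noise-free
linear-bias tracks); in general a second pass shifts values at the
noise/√(window) scale. The tests assert idempotence only where it holds
mathematically.

## Peak calling and the ChIPScore

The corrected track is smoothed by **two rounds** of centered moving
averaging over **29 probes** (≈ 320 bp at 11 bp spacing). Windows wrap
around the origin when the chromosome is circular, otherwise they truncate
at the ends. A probe is a maximum (minimum) iff its smoothed value equals
the maximum (minimum) over the smoothing window centered on it; runs of
exactly tied candidates collapse to their leftmost probe, which matters on
noise-free synthetic tracks where long exact plateaus occur. Maxima within
**300 bp** are merged by single linkage, the cluster represented by its
highest (leftmost on ties) maximum.

Peak height is the smoothed maximum minus the **mean of the two flanking
minima** (the nearest minimum on each side; a single flank is used at a
linear track end), clipped at zero. The source procedure names both adjacent
minima without stating a combination rule; the mean is symmetric and uses
both values, and heights are invariant under adding a constant to the track
either way. Each peak's ChIPScore is

    ChIPScore = (height − median(H)) / (Q3(H) − median(H))

over all peak heights H of the same replicate, with quantiles by linear
interpolation of order statistics (no convention is canonical; this is
numpy's default and the one under which the identity "height at Q3 scores
exactly 1" holds). The score is undefined (error) for fewer than 4 peaks or
a degenerate height distribution (Q3 = median), which on real-scale tracks
does not occur — a tiling array yields hundreds of noise maxima per
replicate, and it is precisely that noise bulk the score normalizes against.

Replicate reconciliation: maxima of the two replicates are matched greedily
by ascending pairwise distance within **300 bp**, each peak used at most
once; pairs with ChIPScore **≥ 4.0 in both replicates** become consensus
peaks at the rounded midpoint, scored with the mean of the two replicate
scores. Greedy nearest-first matching and mean-combination are this
package's choices; the cutoff-in-both rule makes the consensus count
monotonically non-increasing in the cutoff.

## PWM scanning with exact p-values

`build_pwm` tallies per-column base counts from user-supplied equal-length
aligned sites and converts them to probabilities with a pseudocount
(default **0.25 per cell**; any positive value keeps log-odds finite).
Windows are scored in bits against a zero-order background; the default
background is the scanned sequence's own mononucleotide composition,
symmetrized across strands (A=T, C=G, Laplace-smoothed), so a sequence and
its reverse complement produce identical hit sets. Uniform or explicit
backgrounds are available.

Per-column log-odds are quantized to a **1e-3 bit** grid, and that quantized
score is used *everywhere*: by the scanner, by the p-value dynamic
programming, and by any enumeration. The DP convolves the four-point
per-column score distributions into the exact pmf of the integer window
score, so tail probabilities are exact (to float accumulation, < 1e-12) for
the score function actually applied; quantization perturbs the ideal
log-odds of a width-w window by at most w/2000 bits, irrelevant at a 1e-6
p-value cutoff. Thresholds passed to `score_pvalue` are snapped to the grid
with the same rounding rule as the matrix entries.

Scanning reports hits at p ≤ 1e-6 (the conventional raw cutoff for
operator-box searches; no multiple-testing correction, by design) on both
strands, reverse-strand hits by forward-strand start. Ambiguous bases
contribute zero log-odds (background behaviour). Because a palindromic
operator scores on both strands at the same position, opposite-strand hits
overlapping by at least half the motif width are deduplicated to the
better-scoring strand. A peak is *box-associated* when a hit starts within
**±50 bp** of the peak maximum (half the 100 bp window conventionally used
to extract peak sequences for motif discovery).

## Peak classification

Distance from a peak maximum to a translational start is signed along the
gene's strand: negative upstream of the start codon's first base, positive
downstream. The nearest start over all genes on both strands is used, ties
on |distance| broken toward the gene for which the peak is upstream.
Categories:

- `promoter_proximal`: −200 ≤ d < 0;
- `intragenic`: d > 200 and the peak lies inside a CDS;
- `start_overlap`: 0 ≤ d ≤ 200 inside the CDS — kept as its own class so
  that neither published class is silently inflated by sites sitting on the
  start codon itself;
- `distal`: everything else.

Categories are mutually exclusive and exhaustive by construction, re-derivable
from the stored distance and containment, and invariant under mirroring the
genome (reverse complement with coordinate reflection).

## The synthetic tiling-array generator

`simulate` provides the study conditions every end-to-end guarantee is
measured under. Defaults: a **200 kb** circular chromosome at **43.5% GC**
(a *B. subtilis*-like composition), CDSs of 400–1500 bp separated by
60–400 bp gaps (~80% coding), probes every **11 bp** (so the 29-probe window
spans ≈ 320 bp), **20 planted sites** — half promoter-proximal (80–180 bp
upstream of a start), half intragenic (≥ 280 bp inside a CDS) — at
**8–32×** fold enrichment with ≥ 2 kb separation, a 20-nt palindromic
operator box written into the sequence at each site, and two replicates.

Signals follow log2 WCE ~ N(10, 1); expected enrichment at a probe is
Σ log2(fold)·max(0, 1 − d/W) over sites, a **triangular kernel** of
half-width **W = 500 bp** — a first-order model of sonicated-fragment
coverage with a closed form convenient for testing, wrapping around the
origin; IP = WCE · 2^(E + g(A) + ε) with per-probe noise ε ~ N(0, 0.25) and
a polynomial dye bias g (default −0.3 + 0.25A − 0.02A², a mildly curved MA
cloud of realistic ~0.5 log2-unit amplitude). Because A itself depends on
IP, g is evaluated at the pre-noise average intensity A = log2 WCE + E/2;
this breaks the circularity while keeping M a smooth function of observed A,
which is what the loess step assumes. The planted category label is only
recorded if the site's neighbourhood (±50 bp, the array's effective
positional resolution) actually classifies as intended under the
nearest-start rules — gene packing is dense enough that a site placed
against one gene can sit closer to a neighbour's start.

What the generator does **not** emulate: probe-sequence-specific
hybridization efficiency, saturation, spatial array artefacts, copy-number
variation, replicate-correlated noise, or degenerate/partial operator
boxes (unless `box_fraction < 1`). Passing the recovery criteria therefore
shows the pipeline's logic is correct under its own model assumptions — with
well-separated strong sites recovery is essentially perfect (20/20 within
≤ 15 bp, no spurious consensus peaks) — not that real arrays, with
correlated probe effects and weak or clustered sites, will be as clean.

## Problem sizes and numerical choices

The validation study uses the 200 kb default genome (18 181 probes per
replicate), which exercises every code path including origin wrap-around at
interactive runtimes; brute-force cross-checks run on tracks up to 2 000
probes and motifs up to width 8 (65 536 enumerated sequences), where
exhaustive oracles are exact and cheap. Other constants: smoothing equality
is asserted bitwise (implementation and oracle reduce windows in the same
order); loess recovery bounds are 0.01 on noise-free nulls away from A-range
edges and ±0.02 for A-binned non-peak means when planted peaks occupy < 5%
of probes; consensus positions round half up at the circular midpoint.

## Known limitations

- The ChIPScore presumes hundreds of detected peaks per replicate; on short
  or heavily smoothed tracks with few maxima the quartile normalizer is
  unstable (and an error below 4 peaks).
- Greedy replicate matching is not globally optimal; with peaks spaced
  ≥ merge-window apart the difference never materializes.
- The scanner's background is zero-order; CpG-style dinucleotide composition
  biases are not modelled.
- Linear (non-circular) tracks lose one flanking minimum at each end; peak
  heights there lean on a single flank.
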