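# Methods

`c4map` implements the quantitative core of an indirect G-quadruplex (G4)
mapping strategy. When the G-rich strand of genomic DNA folds into a G4,
its complementary C-rich strand (here called **C4**) is left exposed as
single-stranded DNA. A small engineered probe that recognizes C-rich ssDNA
therefore reports G4 formation from the opposite strand. The package
covers the three quantitative layers of that strategy — sequence grammars,
binding thermodynamics, and genomic colocalization — plus seeded synthetic
data generators that make every layer testable without sequencing data.

## Motif grammars (`c4map.seqscan`)

All grammars are built from **maximal runs** (tracts) of a single base
joined by loops. Maximality makes parsing unambiguous: a hit's first and
last tract cannot be extended, and a run shorter than the tract minimum is
ordinary loop content.

* **Probe unit** — the minimal element the C-rich-ssDNA probe binds: two
  maximal C-tracts of ≥ 3 C separated by a 1–7 nt spacer (CCCN₁₋₇CCC), or
  one uninterrupted run of ≥ 7 C. A lone 6-C run is deliberately *not* a
  unit: binding to 6 C without a spacer was detectable only at very high
  probe concentration, so the single-run threshold sits at 7.
* **C4** — chains of maximal C-tracts (≥ 3 C) joined by 1–7 nt loops. The
  canonical G4 complement has four tracts; because probe binding is
  detectable from two tracts up, `scan_c4` accepts `min_tracts` ∈ {2,3,4}.
  Each hit is a *maximal* chain, which realizes leftmost-greedy resolution
  with maximal tract count and makes the four-tract hit set nest inside
  the two-tract hit set.
* **PQS classes** on the G-rich strand: `canonical4G` (four G≥3 tracts,
  loops 1–7), `twoQuartet` (four G≥2 tracts), `GVBQ` (exactly one
  length-2 GG tract among four, the others G≥3), `longLoop15` (four G≥3
  tracts, loops 1–15 with at least one ≥ 8 — disjoint from `canonical4G`
  by construction), and `bulged` (four tracts of which exactly one is
  split by a 1–3 nt non-G bulge, combined G-count ≥ 3). The `GVBQ`,
  `longLoop15` and `bulged` definitions follow the common scanner
  conventions for these variant classes; where published pipelines differ
  in detail, the parameters here are the documented defaults.

Scanning covers both strands: minus-strand hits are reported in
plus-strand coordinates with `strand="-"`. Loops may contain any base
except N (a hit never crosses an assembly gap, and N also never counts as
tract or spacer content). Overlap resolution is deterministic:
leftmost-greedy, preferring more tracts, then longer span, independently
per strand. Hits on opposite strands may interleave (a G-run can sit
inside the loop of a C-chain), so the non-overlap guarantee is per
(sequence, class, strand).

Every scanner is checked in the test suite against an independent
brute-force enumerator (explicit character walks, exhaustive window
enumeration, the same greedy resolution re-derived), and C4/canonical-PQS
strand duality — `scan_c4(S, 4)` equals the mirror of
`scan_pqs(revcomp(S), "canonical4G")` — is asserted exactly on random
sequences.

## Binding isotherm (`c4map.isotherm`)

EMSA titrations hold the labelled DNA at T0 = 20 nM, which is comparable
to the dissociation constants being measured, so the hyperbolic isotherm
is invalid and the **tight-binding (ligand-depletion) quadratic** is used:

    Y(X) = [T0 + X + Kd − sqrt((T0 + X + Kd)² − 4·T0·X)] / (2·T0)

with X the total protein concentration. Y is the bound fraction computed
from gel bands as `1 − free/total` (the free band is what *remains*
unbound; the bound fraction rises with protein and is 0 at X = 0). The
closed form is verified against a numerical mass-action equilibrium
solver to 1e-9 and reduces to X/(X+Kd) in the dilute limit.

**Fitting.** Kd is the single free parameter (T0 is known). `fit_kd`
minimizes the residual sum of squares on a fixed 1201-point log₁₀ grid
spanning 0.1 pM–10 mM and refines the bracketing interval with bounded
scalar minimization in log-space (xatol 1e-12). This is deterministic,
derivative-free, and needs no starting guess; noiseless titrations at the
printed gradient recover planted Kd values of 10.79, 84.86 and 394.1 nM
to ~1e-8 relative error. A series with no binding signal, or an optimum
pinned to the search boundary, reports `converged=False`. An optional
saturating-amplitude parameter is intentionally absent by default: the
quantity fitted is the bound fraction itself.

**Bootstrap.** The original quantification reported point estimates only;
`bootstrap_ci` adds a residual-resampling bootstrap: residuals from the
point fit are mean-centered, inflated by sqrt(n/(n−p)) (p = 1), resampled
with replacement onto the fitted curve, and each replicate refit; the CI
is the 2.5–97.5 percentile range, clamped to contain the point estimate.
Replicate refits use the same objective on a windowed log-grid with two
parabolic refinement passes (relative error ≪ 1e-6), vectorized across
replicates. Known limitation: with only 8 titration points — of which
roughly half carry little Kd information (the X = 0 anchor and the
near-plateau top points) — any residual-based noise estimate is volatile
and biased low, and the nominal-95% percentile interval is
anti-conservative at realistic noise levels. The coverage experiment in
the acceptance test suite quantifies this; treat the intervals as
indicative rather than exact.

## Colocalization statistics (`c4map.coloc`)

* `rpgc_normalize` — one global scale factor bringing the genome-wide
  mean bin value to 1 (1× coverage), the bin-level equivalent of
  reads-per-genomic-content normalization.
* `track_correlation` — tracks re-binned to 300 bp (default) by
  averaging, bins intersecting a user-supplied blacklist dropped, and
  optionally, per pair, bins where either track exceeds its own
  median + 200×MAD dropped (the outlier heuristic is configurable; a
  track whose MAD is zero skips the filter). Pearson by default,
  Spearman behind a flag. Correlation is invariant under positive affine
  per-track scaling.
* `overlap_fraction(A, B)` — fraction of A peaks overlapping some B peak
  by ≥ 1 bp (configurable); deliberately asymmetric, as peak-overlap
  percentages are reported per numerator set.
* `upset_counts` — the union of all intervals is merged and each merged
  interval is assigned to the exact subset of input sets it touches, so
  counts sum to the number of merged union intervals. A raw-per-peak
  alternative was considered and rejected as the default because merged
  counting makes the "each element counted once" invariant exact.
* `profile_matrix` — rows are region midpoints ± flank sampled at the
  requested resolution by per-base averaging of track bins; positions
  outside the binned chromosome extent contribute 0. Rows are ranked by
  descending mean with stable ties. Midpoints (not summits) anchor the
  rows because peak files need not carry summit information.
* `promoter_partition` — a hit is "promoter" iff it overlaps
  [TSS − 3 kb, TSS + 3 kb] (half-open implementation
  `[tss−w, tss+w+1)`) for any TSS; the TSS of a minus-strand gene is
  `end − 1` under the half-open convention. The partition is exhaustive
  and disjoint.
* `mean_signal_at` — column-mean anchor profile with minus-strand rows
  reversed, so composites read 5′→3′ of the gene.

All coordinates are 0-based half-open throughout; trailing partial bins
at chromosome ends are dropped so every bin has equal width (matching
fixed-bin summary tools and keeping correlations unweighted).

## Synthetic data (`c4map.synth`)

The generators emulate the statistical structure the analyses assume and
carry exact ground truth; all are bit-reproducible under a fixed seed.

* `make_genome` — i.i.d. background at a chosen GC (default 0.41,
  human-like) with grammar-drawn motifs (tract lengths 3–5, loops 1–7)
  planted on random strands, non-overlapping, ≥ 20 bp apart. Planted
  loops are drawn from {A,T} (the experimental spacer series varied T
  runs), so a motif can never contain a second, accidental tract.
  Background is assembled from ≤ 2 kb blocks, each rejection-resampled
  until it contains no hit of any planted class on either strand, and
  block junctions plus the 16 bp flanking every plant are A/T-only — 16
  exceeds the longest loop (15 nt), so no grammar can chain across a
  junction. Consequently the truth BED is *exhaustive*: scanning the
  genome for a planted class returns exactly the planted intervals (one
  class per genome when classes subsume one another, e.g. GVBQ plants
  also satisfy the two-quartet grammar). What this background does not
  model: repeat structure, isochore GC variation, CpG islands, or any
  correlation between motifs and chromatin context — so exact planted
  recovery validates the scanner's logic, not its genome-wide
  false-positive rate on real DNA.
* `make_peak_pair` — two peak sets with an exactly controlled fraction
  of A peaks overlapping B, built from disjoint genomic slots (slot
  width 4× the 400 bp default peak length); `round(frac·n_a)` slots hold
  an overlapping pair with a random ≥ 1 bp shift, the rest hold lone
  peaks. Overlap statistics on the output are exact by construction.
* `make_coverage` — per-bin Poisson counts at a background rate
  (default 10 counts/bin) with a triangular enrichment ramp to
  `background_rate × enrichment` (default 10×) at peak centers. Real
  CUT&Tag tracks additionally carry fragment-length structure,
  GC/accessibility bias and duplicate artifacts, none of which are
  modelled — correlations measured on these tracks test the statistics,
  not sequencing realism.
* `make_titration` — bound fractions from the quadratic isotherm at the
  experimental gradient (0, 1, 3, 10, 30, 100, 300, 1000 nM protein,
  T0 = 20 nM) plus additive Gaussian noise on Y, clipped to [0,1].
  Clipping mirrors what densitometry can report; it makes the effective
  noise heteroscedastic near Y = 0 and Y = 1, which is one driver of the
  bootstrap's anti-conservatism above.

## Problem sizes

The shipped analyses and tests run at desk scale by choice: a 1 Mb
single-chromosome genome with 50 planted C4 motifs, 200/220-peak sets, a
6 Mb coverage space (120k bins at 50 bp, 20k at 300 bp), 8-point
titrations with 1000 bootstrap replicates, and 200-replicate coverage
experiments. These sizes are large enough to pin every statistic to its
expected value (sampling bounds ~2/√n are asserted where relevant) while
keeping the full suite in the low minutes.

## Degenerate inputs and tie-breaks

Empty peak sets are rejected where a fraction would be undefined;
all-zero tracks cannot be RPGC-normalized; titrations need ≥ 3 distinct
concentrations and at least one positive bound fraction to fit; profile
row ranking breaks ties by input order; upset membership and promoter
assignment use ≥ 1 bp overlap; `fraction_from_gel` tolerates free > total
only within 1e-9 relative (band quantification noise) and clips to [0,1].
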