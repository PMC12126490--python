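# Methods

This note documents the models, conventions and numerical choices behind
each analysis, what the synthetic-data generators do and do not emulate,
and the design decisions taken where more than one convention exists.

## Repeat-family enrichment

Per locus, fold enrichment is the ratio of CPM-normalized ChIP to
CPM-normalized input counts; ChIP and input each use their own library
total, so the statistic is invariant to rescaling either library. Loci
with fewer than 1 input read are removed before the ratio is formed — this
single rule is both the coverage filter and the guard against division by
zero; no pseudocount is added. Families are summarized by the median
(mean of the central pair for even n), which tolerates the heavy right
tail that a few high-copy outlier loci produce.

Per dataset, family medians are standardized to mean 0 and **sample** SD 1
(n−1 denominator; with hundreds of families the distinction from the
population SD is negligible, but the convention is fixed and tested). A
dataset whose medians are constant has no meaningful z-scores and is
rejected rather than silently zero-filled. A family left without any
surviving locus in some dataset is dropped from the matrix entirely (with
a warning) so every z-score column stays well-defined; imputation was
rejected because a NaN-bearing column would break both the normalization
invariant and the clustering distance.

Clustering uses d(u,v) = 1 − Spearman ρ(u,v) with average linkage. Rows
are pre-sorted lexicographically by label before linkage so equal-distance
merges resolve deterministically. A constant row makes ρ undefined and is
reported by name. d ranges over [0, 2]; two rows related by any strictly
monotone transform are at distance 0, reversed rankings at distance 2.

## LTR anchors and profiles

"Same genomic integration" is resolved through the annotation's
integration id; for flat BED input without ids an inference mode groups
same-family, same-strand runs with gaps ≤ 1,000 bp. Which subfamily names
are LTRs is supplied as a family → LTR-subfamily map (mirroring how repeat
libraries name LTR vs internal segments); 5′ vs 3′ is then decided
strand-awarely by position within the integration. Where both LTRs are
present only the 5′ LTR is kept; orphan and single-LTR integrations are
kept as-is; two 5′-LTR records in one integration is a malformed
annotation and an error.

The anchor is the strand-aware 5′ boundary of the kept LTR (interval start
on +, interval end on −). Windows are anchored, not centered: the default
−1,500/+8,000 bp span covers the upstream flank and the body of a typical
full-length element. Bin size defaults to 50 bp (the window must divide
evenly). Minus-strand windows are reflected so "upstream" is biological
upstream; the per-bin value is the mean per-base signal, and bins
extending past chromosome ends are masked and excluded from column means
rather than clipped to zero (clipping would drag edge averages toward 0).
Average profiles report per-bin mean ± SEM over unmasked rows.

Differential accessibility uses a two-sided Wilcoxon rank-sum test per
family on per-LTR counts: exact null when the combined sample size is ≤ 25
with no ties, otherwise the normal approximation with continuity and tie
correction. Benjamini–Hochberg adjustment spans exactly the families
tested in one invocation; adjustment across assays is out of scope.
Samples are treated as independent (different cell lines/conditions, not
paired measurements).

## Genome bins and track correlation

Bins tile each chromosome from coordinate 0 at a fixed width (default
5 kb), the last bin truncated, so binning conserves total signal exactly.
Bins with zero signal in both tracks are retained — removing them would
change the rank distribution. Spearman p-values are exact (full
enumeration over the n! pairings of the rank vectors, using the tie-free
closed form ρ = 1 − 6Σd²/(n(n²−1))) for tie-free vectors up to n = 9 and
use the t-approximation otherwise; at genome-wide n an "exact" setting in
any implementation silently falls back to an approximation, and this
package makes the fallback explicit and testable.

## Binding isotherm

The quadratic (ligand-depletion) isotherm treats free and bound protein
explicitly, which matters whenever the protein concentration is comparable
to K_d. The discriminant (L+P+K_d)² − 4PL is clamped at zero before the
square root: at exact stoichiometric saturation with K_d = 0 it vanishes
analytically and can go marginally negative in floating point. Fitting
uses least squares with K_d bounded ≥ 0, initialized at ΔI_max = the
largest observed response and K_d = the ligand concentration of half-max
response (linear interpolation); at least 4 points are required and a flat
series is rejected. Standard errors come from the fit covariance;
replicates are summarized as mean K_d ± sample SD with n. Concentration
and intensity units are opaque to the code — only internal consistency is
assumed.

## Chemical shift perturbations

Two standard combined-shift metrics are computed per residue: the
Euclidean form √(ΔδH² + (ΔδN/5)²) and the weighted absolute sum
|ΔδH| + α|ΔδN| with α = 0.105, the ratio of the backbone ¹H to ¹⁵N shift
ranges in an HSQC. Both are absolutely homogeneous (scaling the shift pair
by c ≥ 0 scales the metric by c); no fixed inequality between them is
assumed.

Peak matching is a global assignment problem: the Hungarian algorithm
minimizes the total Euclidean-metric distance over apo–bound pairs, with a
pair admissible only inside the (tol_h, tol_n) ellipse (defaults 0.05 and
0.5 ppm; infeasible pairs carry a cost larger than any feasible total, so
the matched count is maximized first). Greedy nearest-neighbour matching
was rejected because two shifted peaks can each sit nearest to the same
bound peak. An unmatched apo peak with no admissible bound peak of
intensity ≥ 0.2 × its own is called disappeared (exchange broadening);
otherwise it is left unassigned. The tolerance and intensity-floor
defaults are package conventions, surfaced as parameters.

## FRAP dip depth

In half-bleach FRAP of a condensate, a transient intensity dip of the
non-bleached half reports internal mixing: unbleached molecules diffuse
into the bleached half faster than exchange with the surroundings refills
the compartment. The unbleached trace (normalized to a pre-bleach baseline
of 1) is smoothed with a Savitzky–Golay filter (window 11 frames, order 3
by default — enough smoothing to suppress frame noise without attenuating
a dip that spans tens of frames) and the dip at probe time t is
1 − min(smoothed) within a symmetric window (default ±5 s) around t,
clipped to [0, 1]. Only this dip readout is implemented; full
reaction–diffusion FRAP modeling is out of scope.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of their arguments including the seed, each
drawing from an RNG stream derived from (seed, operation name) so reusing
one config across generators cannot couple their draws.

* **Annotations** place per-family integrations uniformly at random
  without overlap on one synthetic chromosome; full-length elements are
  contiguous LTR–internal–LTR triples on one strand (default LTR 350 bp,
  internal 5 kb, roughly ERV-like), orphans are solo LTRs (default 30%).
  Real annotations have nested/truncated elements, multiple chromosomes
  and mappability structure; none of that is emulated.
* **Counts** are negative binomial parameterized by (mean, dispersion);
  variance = m + m²/r. Overdispersion is the generic property of ChIP
  count data; dispersion defaults to 10 (moderate overdispersion) and
  input mean to 20 fragments per locus, and the Poisson limit replaces NB
  sampling above dispersion 10⁶. ChIP means are the planted enrichment
  factor × input mean × the ChIP/input library-size ratio, so CPM
  normalization is exercised non-trivially. GC bias, locus-length effects
  and duplicate structure are not modeled, so passing recovery tests shows
  the statistics behave as designed under clean overdispersed sampling,
  not that they are robust to every artifact of real libraries.
* **Titrations** come from the exact forward isotherm plus Gaussian noise;
  **peak lists** sit on a jittered grid separated well beyond matching
  tolerances, with planted shifts/disappearances; **FRAP** curves are
  1 minus a Gaussian transient of planted depth and width 2 s plus noise.

## Problem sizes and tolerances

The recovery studies use 20 families × 100 loci × 3 datasets for
enrichment (planted factors {1, 2, 8}; with grouped factors the
planted-vs-median Spearman ρ has a tie ceiling of ≈ 0.943, which perfect
recovery attains), 200 families × 30 anchors for the null calibration of
the Wilcoxon/BH procedure and 50 repetitions of 20 families × 30 anchors
for its power against a 4× loss, 100 repetitions for noisy K_d recovery
(1% noise, median relative error ≈ 4%), and exhaustive assignment oracles
up to 10 peaks. Exact-equality checks (pipeline vs straight-line
recomputation, profile matrices vs per-base averaging) use 1e−12
absolute tolerance; closed-form formula checks use 1e−12 to 1e−15.
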