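# Methods

## Signal reduction

Coverage is binned at 5 kb (coarse enough to attach Hi-C information to
the same grid) by length-weighted mass: a bin receives
Σ value·bp-overlap over intervals, so binning conserves total signal.
Depth normalization is per track: `cpm` rescales each column to a sum of
10^6; `rpkm` additionally divides by bin length in kb (chromosome-end
bins may be short). The variance-stabilizing transform is
z = (log10(x + c) − mean)/SD per track with pseudocount c = 1 and
*population* SD (divide by n); a zero-variance track is rejected by name
rather than silently producing NaNs.

PCA runs on the transformed (standardized) matrix by default. The choice
is deliberate: running PCA on correlation-like input yields near-equal
positive loadings when the tracks genuinely co-vary, which is the regime
the reduction assumes; a flag (`pca_on_transformed=False`) runs it on
normalized raw values instead. PC1's sign is arbitrary, so it is oriented
to correlate non-negatively with the per-bin mean signal ("more activity
= higher PC1"); if that correlation is exactly zero (perfectly
anti-correlated columns) the first loading is made non-negative instead.

## Segmentation

The boundary model is piecewise-constant means with Gaussian errors —
the intercept-only multiple-structural-breaks setting. For a fixed break
count m the optimal break positions minimize RSS exactly via the
standard dynamic program over a precomputed segment-cost matrix
(O(n²·m)); m ∈ [0, max_breaks] is selected by
BIC(m) = n·ln(RSS_m/n) + k·ln n with k = 2m + 2 (m break dates, m+1
means, one variance), smallest m on ties. The F-statistic (structural
break test) per boundary is exposed for reporting; break *placement*
under the F-test view and the RSS view coincide, so selection via BIC is
the implemented criterion.

Exact search is quadratic, so chromosomes are scanned in 1000-bin
windows stepped by 500 (the final window is right-anchored at the
chromosome end so tails get full context; chromosomes shorter than a
window are one window). The minimum segment size is ceil(5% of the
window) = 50 bins = 250 kb, which also caps breaks per window at 19.

Two merge rules turn window-level breaks into genome boundaries:

- *Margin filtering.* A break sitting exactly at the admissibility
  margin (min_seg from a window edge) usually marks a changepoint lying
  beyond the margin that the constraint pushed inward; it is discarded
  unless that window edge is a chromosome end. The overlapping
  neighbouring window sees the true position unconstrained, so no real
  boundary is lost. Without this rule, a margin artifact entering the
  merge cluster drags the merged boundary tens of bins off target.
- *Clustering.* Remaining breaks are single-linkage clustered with gap
  tolerance = min_seg (two boundaries closer than one minimal segment
  cannot both be real) and each cluster is replaced by its (lower)
  median. Both the tolerance and the window-level selection criterion
  are parameters, since the merge rule is a genuinely open design point.

## Enhancer annotation

Enhancer bins require Z ≥ 1 (inclusive) *jointly* on the H3K27ac and
accessibility tracks; Z ≥ 1 corresponds to roughly the top 5% of the
transformed signal. Counts are aggregated per segment (a bin belongs to
the segment containing its start).

The null for a segment of L bins re-places an L-bin interval uniformly
across the genome (chromosome chosen proportional to its valid start
positions — genome-wide uniform; a chromosome-matched mode exists behind
a flag) 1000 times. Since this null depends only on L, fits are shared
across segments of equal bin length. The shuffled counts are fitted by
maximum likelihood to a zero-inflated negative binomial
P(0) = π + (1−π)·NB(0; μ, θ), P(k>0) = (1−π)·NB(k; μ, θ), optimized on
(logit π, log μ, log θ) with L-BFGS-B from three moment-guided starts
(the mixture likelihood has local optima), ftol 1e-8; the convergence
flag is reported honestly. An all-zero background is degenerate: π = 1,
converged = false, and the tail for observed ≥ 1 is treated as
≤ 1/n_shuffles (label enriched). The p-value is the upper tail
P(X ≥ obs); the enrichment score is log2((obs+1)/(exp+1)) with exp = the
empirical mean of the shuffled counts, so "positive" ⇔ observed above
background mean with a pseudocount guarding zeros. A segment is
enhancer-enriched iff p < 0.05 AND enrichment > 0 — raw p by design; a
Benjamini–Hochberg flag exists but is off by default. `fit_zinb`
requires ≥ 30 counts; AIC model comparison against NB, Normal, and
Tobit-Normal (latent normal left-censored at 0; counts > 0 enter the
density, zeros the censoring mass) uses k = 3, 2, 2, 2.

## Contact integration

Only intra-chromosomal contacts are scored (the 2-Mb cap plus the decay
of informative normalized contacts makes inter-chromosomal entries
meaningless here). Pair pooling takes the *median* of contributing
contact scores per segment pair, including the intra-segment entry; the
segment distance anchor is the gap between closer ends (0 if adjacent),
the most permissive reading; midpoint distance is available behind a
flag. Pairs beyond d_max = 2 Mb or with no contacts are absent.

The score cutoff is estimated by permutation: segment coordinates are
re-placed at random (lengths preserved, placement rule as in the
background shuffle) 100 times; since a tiling segment set cannot be
re-placed without collisions, permuted segments may overlap and their
pair medians are computed by pairwise membership rather than the tiling
lookup. The objective at each grid cutoff c (default grid: integers
spanning the observed score range) is N_true(c) − mean N_perm(c) over
entries with median ≥ c; the argmax is returned with ties toward the
smallest cutoff. With several conditions, per-condition objectives are
averaged before the argmax. The conventional external-score cutoff 17
is only a default for externally normalized tracks; for the fallback
normalizer (log2 observed/expected with distance-stratified expected
counts and α = 1 pseudocount) the scale differs and the cutoff must be
re-estimated.

PTC calling binarizes the table: an edge joins two distinct
enhancer-enriched segments iff median ≥ cutoff (inclusive) and distance
≤ d_max; a segment qualifies alone iff its intra-segment entry passes.
PTCs are connected components (networkx) of that graph — singleton hubs
are legitimate.

## Downstream classes and candidate genes

Condensate = enriched ∧ in a PTC; Enhancer = enriched ∧ not;
enhancer-depleted segments split into Active (mean PC1 > 0) vs Repressed
(≤ 0). The PC1-sign rule is a documented stand-in — the category
boundary is exposed as a parameter — justified by PC1's positive
correlation with every activity track. Gene-to-category assignment is
exclusive: a gene straddling two categories is listed in neither.
Candidate selection per condition requires PTC-span *overlap* (the
permissive reading of "within"), TPM > 0, and ≥ 1 enhancer bin touching
[TSS − 5 kb, TSS + 5 kb]; across an ordered condition series the
candidate flag marks genes passing in every later condition but not the
first (condensate recruitment specific to the induced stages).

## Synthetic fixtures

The default fixture is two 7.5-Mb chromosomes (1500 × 5-kb bins each;
small enough for exhaustive oracles), seven 60–80-bin planted segments
of elevated regional mean, and three hubs of 2–3 enhancer regions with
members within 2 Mb and distinct hubs separated by > 2 Mb (or a
chromosome), so each must surface as its own condensate.

Design choices a reader should know:

- *Enhancer regions coincide with their planted segments* and are dense
  (density 0.9). With a 3000-bin genome the shuffled-count null is
  dominated by whether a random placement aligns with a region; only
  when the truly enriched segment is enhancer-dense end to end does its
  observed count (~54 of 60 bins) exceed what any misaligned placement
  can collect, giving unambiguously small p-values. Sparse enhancer
  islands inside large segments are *not* represented in the default
  fixture.
- *The regional mean structure is carried by the non-mark tracks*
  (H3K4me3-like, TF-like), while the mark tracks are flat plus the joint
  enhancer boost (+80 on both marks over baseline 4, noise SD 1). This
  keeps the joint Z ≥ 1 call specific to planted enhancer bins — if the
  marks also carried the broad elevation, entire elevated segments would
  pass the Z threshold and the planted "enhancer bin" truth would be
  meaningless.
- *Contacts*: 12000 background contacts per chromosome with
  exponentially decaying gaps (scale 150 bins, capped at 400+50) scored
  N(0, 1); any contact with both ends inside one hub's regions is
  re-scored N(20, 1) — in a normalized track, contacts within an
  interacting hub score high throughout, they are not a minority
  admixture — plus 40 guaranteed contacts per hub region pair (including
  each region with itself, exercising the intra-segment/singleton rule).
- Noise is Gaussian truncated at zero, not read-level Poisson (a
  `poisson` noise model exists); bedGraph output writes per-bp rates so
  re-binning recovers the matrix exactly.

A green end-to-end test therefore establishes: boundary recovery at
step/noise = 5, correct joint enhancer calling, ZINB calibration on this
null, separation of a 20-SD contact-score gap, and exact hub/component
recovery. It does not establish performance on sparse enhancer islands,
on score gaps near the background tail, on real read noise, or at
genome scale.

## Numerical notes

- Segment costs use prefix sums; tiny negative round-off is clipped at 0.
- BIC uses −inf for RSS = 0 (a perfect fit wins; among perfect fits the
  smallest m wins by the penalty).
- Median of an even cluster/count set is the lower median for integer
  boundary positions (numpy's interpolated median for scores).
- All randomness flows through `numpy.random.default_rng(seed)`;
  identical seeds give bit-identical shuffles, permutations and
  fixtures. The sliding-window segmentation itself is deterministic.
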