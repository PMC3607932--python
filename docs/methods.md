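# Methods

## Scope and model of the data

The package treats an activated-sludge *Archaea* community as observed
through three instruments: an 82-clone 16S rRNA gene library (a multinomial
sample of the community), dual-enzyme T-RFLP fingerprints (relative peak
heights of terminal restriction fragments as abundance proxies), and
three-channel FISH images (area fractions as biomass proxies). Each assay
has its own module; a synthetic module generates inputs for all of them
with planted ground truth.

## Clone-library statistics

**Distances.** Pairwise distances are uncorrected p-distances with pairwise
gap deletion: the fraction of differing positions over columns where both
sequences carry a non-gap character. The similarity thresholds used for OTU
assignment (98.7%, 95%, 90%, 80%) are identity conventions, so an
evolutionary-model correction would shift sequences relative to the
convention rather than improve it; p-distance is therefore the default and
the distance matrix is an ordinary `skbio.DistanceMatrix`, so a corrected
matrix can be substituted.

**Clustering.** OTUs are complete-linkage (furthest-neighbor) clusters:
merging stops when the smallest inter-cluster diameter exceeds
`1 − threshold`. Complete linkage guarantees every OTU's internal diameter
respects the threshold and makes partitions at nested thresholds properly
nested. Ties are broken by the lexicographic order of each cluster's
smallest member id, which fixes the output completely. The implementation
is a direct O(n³) agglomeration (clone libraries are small); tests
cross-check it against `scipy.cluster.hierarchy` complete linkage on
tie-free matrices and against exhaustive partition enumeration on ≤ 6
sequences.

**Richness.** Chao1 is the classic form `S_obs + f1²/(2 f2)` with the
`f2 = 0` fallback `S_obs + f1(f1−1)/2`. The bias-corrected variant is not
used: on the survey's count table (f1 = 12, f2 = 4) the classic form yields
the published estimate of 43 while the bias-corrected form does not.
Coverage is `100·S_obs/Chao1`.

**Accumulation.** The collector's curve is the permutation mean (default
1000 permutations, seeded) of distinct OTUs among the first k clones;
`expected_accumulation` provides the exact hypergeometric closed form
`E[S_k] = S − Σᵢ C(n−nᵢ, k)/C(n, k)` as an oracle.

**Evenness.** The Pareto-Lorenz curve ranks OTUs by descending abundance
and plots cumulative abundance share against cumulative OTU share; Fo is
100·y at x = 0.2, linearly interpolated between vertices when 0.2·S is not
integral (for S = 25 no interpolation is needed).

## In-silico digestion

The label origin is the first base of the forward primer (the fluorophore
sits on its 5′ end), and a TRF length is `site + cut_offset − origin` for
the leftmost recognition site at or after the origin — with blunt cutters
AluI (AG^CT) and RsaI (GT^AC) this equals the gel-called fragment size.
Fragments outside the 50–1020 base sizing window are flagged out-of-range
with the raw length retained; no site means ND. Clones that begin 50–100
bases downstream of the primer are placed on a full-length reference by
exact prefix matching (20 bases, required unique) assuming no indels
between primer and clone start; a recognition site on the reference
upstream of the clone start makes the TRF unpredictable (ND). Primer
matching uses IUPAC sets; an N in the target matches nothing.

## T-RFLP pipeline

Steps, in order, with their defaults:

1. **Peak filter** — keep 50 ≤ size ≤ 1020 and height > 50 FU (strict).
2. **Replicate gate** — a sample × enzyme needs ≥ 2 of ≤ 3 replicates with
   total fluorescence (sum of peak heights) > 500 FU; the top two are kept,
   ties resolved toward the lower replicate id.
3. **Normalization** — iteratively scale every profile to the smallest
   total fluorescence and delete scaled peaks ≤ 50 FU (a rescaled peak at
   the detection limit is indistinguishable from noise), repeating until a
   fixed point; the removed fraction of each profile's original
   fluorescence is reported.
4. **Alignment** — pooled peaks sorted by size; a peak joins the current
   bin when within `gap` (default 1.0 base — called sizes treat 184/185 and
   238/239 as adjacent variants) of the bin's running mean, else starts a
   new bin; within one profile, co-binned peaks are summed with a
   height-weighted mean size.
5. **Consensus** — bins present in both replicates, averaging size, height
   and area; relative abundance is mean height over consensus total
   fluorescence.

The same normalization/alignment pass is applied a second time across the
time series of consensus profiles before any between-date comparison.
Consensus profiles with total fluorescence below 25% of the median (a
configurable stand-in for an unquantified "low fluorescence" exclusion) are
dropped there. Manual post-alignment error checking is replaced by the QC
report. The moving-average alignment rule is a reconstruction of a
procedure whose original description is terse; it is isolated behind
`align_peaks` so it can be swapped out.

## Dynamics

Bray-Curtis distances (percent) are computed against the chronologically
first profile. Dual-enzyme identification accepts a database sequence as a
candidate when, for both enzymes, predicted − observed lies within the
drift window, default [3, 7] bases: the observed bias is 4–6 bases
(predictions run long because called sizes run short of true fragment
lengths), widened by ±1 for size-calling jitter. Out-of-range observed
slots match ND/out-of-range predictions. Correlations are Pearson r with a
two-sided t-test (`t = r·√((n−2)/(1−r²))`, n−2 df); a TRF absent from an
existing profile contributes abundance 0 by default (a `zero_fill=False`
flag drops those dates instead — the choice between the two policies is
genuinely open and both are provided); dates missing either value are
dropped pairwise. Stars use the conventional 0.05/0.01/0.001 levels; no
multiple-testing correction is applied, matching the reporting convention
of this literature, and the table should be read accordingly. The
"Observations" count reports the profiles in which the TRF appears,
separate from the pair count used for the test.

## FISH quantification

Channels are thresholded strictly above 100 (8-bit assumption,
configurable). Pixels positive for the bacterial channel AND an archaeal
channel are removed from all masks as hybridization artefacts. The
archaeal area is ARC915-positive plus MX825-positive-not-ARC915 (the
universal archaeal probe misses some Methanosaetaceae); bacterial area is
the EUB remainder. Images with combined signal area < 1000 pixels show
dispersed cells rather than flocs and are excluded; the exclusion count is
always reported next to the mean. Aggregation is the mean of per-image
percentages with its sample SD (a pooled-area ratio is available behind a
flag).

## Synthetic data

The generator emulates: a skewed (Zipf-like) abundance distribution; taxa
with exactly one AluI and one RsaI site each at controlled positions ≥ 60
bases from the labeled end, giving distinct fragment-length pairs;
replicate electropherograms where each taxon contributes height
`w·H·(1+ε)` with per-replicate signal factor H ~ U[800, 3000] FU (so the
500 FU gate is exercised on both sides after filtering), ε ~ N(0,
noise_sd), and a planted size-calling drift subtracted from the true TRF;
spurious Poisson(2) sub-threshold peaks (10–49 FU) that the 50 FU filter
must remove; parameter series drawn from plant-realistic ranges
(temperature 10–20 °C, SRT 2–4 d, F/M 0.006–0.010, COD ~820–1300 mg/L,
NO₂₃-N 40–56 mg/L, SSVI 65–95 mL/g, effluent NSS 13–33 mg/L; shear
sensitivity, EPS protein and EPS carbohydrate have no published ranges and
use plausible activated-sludge values, 15–25, 20–40 mg/g and 6–14 mg/g)
with linear taxon couplings whose slopes are recorded as ground truth; and
FISH label stacks with a planted archaeal area fraction.

Deliberate simplifications: peak calling from raw traces, size-standard
curve fitting, chimeras, alignment uncertainty and between-run calibration
drift are not simulated, and planted abundance–parameter couplings are
exactly linear. Replicate noise is multiplicative Gaussian — the original
measurement's noise structure is unknown, so this is a configurable
stand-in. Passing tests therefore demonstrate correctness of the
computations and recoverability of planted structure, not robustness to
every artefact of real electropherograms. Abundance tables from
`generate_parameter_series` are not renormalized across taxa, since
renormalization would couple all taxa to every planted parameter and break
the planted linearity the recovery tests assert.

## Numerical choices and problem sizes

All randomness flows through `numpy.random.default_rng` with explicit
seeds; identical scenario + seed reproduces outputs bitwise. Peak
comparisons use strict inequalities exactly where the filtering rules say
"above". Degenerate inputs raise: empty abundance vectors, all-zero
Bray-Curtis pairs, zero-variance correlation series (flagged, not raised),
unmappable clones. The analysis drivers use 8 taxa, 16 sample dates × 3
replicates × 2 enzymes, 82-clone libraries, 1000 accumulation
permutations, 100-run correlation calibrations and 90 synthetic FISH
images of 256×256 pixels per sample — sizes at which every stage's
behavior is already fully exercised and the whole analysis runs in
seconds.

## Known limitations

Complete linkage is one of several defensible linkage rules for OTU
clustering; single or average linkage would give different partitions on
borderline pairs (the linkage is a parameter of `assign_otus` in spirit,
but only complete linkage is implemented). Genus-level Chao1 is computed
but has no published singleton/doubleton counts to check against. The
dual-enzyme identification pairs observed TRFs across enzymes by rank in
the analysis driver, which is only a heuristic for which AluI peak
co-occurs with which RsaI peak.
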