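# Methods

## σ-value model

Reads are assigned to fixed-width bins (default 10 kb) by midpoint, so each
read contributes to exactly one bin and total counts are conserved; trailing
partial bins at chromosome ends are dropped. For a sample with counts c_b
over B unmasked bins, normalised counts are ñ_b = c_b · (m·B / Σc) with
target mean m (default 10), and σ_b = ñ_b / s where s is the sample standard
deviation (denominator B−1) of ñ over unmasked bins. Because the scale
factor cancels between numerator and denominator, σ is exactly invariant to
multiplying all counts by a positive constant — the property that makes σ
comparable across libraries of different depth. The phrase "divided by its
standard deviation" admits several readings; this package uses one SD per
sample computed genome-wide over unmasked bins, the simplest choice that
makes σ a genome-wide z-like score. Two alternatives are exposed:
`sd_scope="chromosome"` (normalisation and SD per chromosome) and
`sd_mode="poisson"` (σ_b = ñ_b / √m, the SD a pure Poisson background would
have). Masked bins carry no σ and are excluded from every statistic.

Smoothing (`smooth_sigma`) is a centred moving average over unmasked bins
with an odd window; the default window of 1 is the identity, so smoothing is
opt-in noise control, not part of the core definition.

## Origin calling and classification

Origins are local maxima of the treated-sample σ track, found independently
per chromosome: a bin is a candidate when σ ≥ `min_sigma` (default 3.0) and
exceeds its nearest unmasked neighbour on each side; a plateau of equal
values higher than both flanks yields its leftmost bin; candidates closer
than `merge_distance_bins` (default 2) merge, keeping the higher-σ bin
(leftmost on ties). Chromosome-edge bins compare against their single
neighbour. The caller is deterministic and is tested against an exhaustive
per-bin scan.

Each called origin gets the adjusted ratio r = σ_treated /
max(σ_control, `control_floor`): r > 4 → induced 4:1; 2 < r ≤ 4 → induced
2:1; otherwise constitutive. Both induced thresholds are strict lower
bounds, so a ratio of exactly 4 is 2:1-induced and exactly 2 is
constitutive — the boundary at 4 is unclassified under a strict reading of
"greater than 4" vs "lower than 4", and this package closes it upward into
the 2:1 class. The floor (default 1.0) is this package's interpretation of
an "adjusted" ratio: it prevents division blow-ups at origins with
essentially no control signal while leaving ratios untouched wherever the
control σ exceeds 1. Peaks are called on the treated track only; the
treated-vs-control comparison is evaluated at those bins. Replicates are
combined by bin-wise averaging of σ tracks before peak calling
(`replicate_combine="pooled_counts"` pools raw counts instead).

`min_sigma = 3.0` is a package default, not a published threshold; all
recovery tests hold with planted peaks well above it (σ ≈ 6–11), so they do
not depend on its exact value.

## Genic context and gene-size enrichment

Gene spans are one collapsed interval per gene (isoforms already unioned);
overlapping genes are unioned for bin classification but kept separate for
hit attribution. A bin is genic only when every base pair lies inside the
gene-span union regardless of strand, intergenic when it overlaps no gene,
mixed otherwise; origin-level summaries collapse mixed into intergenic, so
"genic origin" means wholly intragenic firing. GFF3 input (1-based
inclusive) is converted to 0-based half-open on read; the conversion is
round-trip tested.

A gene "contains" an origin when its span overlaps the origin's bin by at
least 1 bp (`require_containment` demands the whole bin); the hit set is
restricted to protein-coding biotypes. Length enrichment uses a two-sided
Mann–Whitney U: exact by full enumeration of sample assignments (ties via
midranks) when both samples have ≤ 8 observations, scipy's normal
approximation with tie and continuity corrections otherwise. The exact path
matches an independent enumeration oracle in the tests.

## Fibre velocity and ΔΔCt

Fork velocity converts a combined CldU+IdU track length to kb/min as
length_µm × `kb_per_um` / `label_minutes`, defaults 2.59 kb/µm and 40 min
(two 20-min pulses). The conversion constant is the field-standard B-form
DNA density — 1 µm of spread fibre ≈ 2.59 kb — applied over the total
labelling time. Condition comparisons report pooled per-fibre medians
(midpoint convention) with the same Mann–Whitney contract;
medians-of-experiments aggregation is possible by calling the comparison
per experiment.

ΔCt = Ct(target) − Ct(reference) per sample, averaging technical replicate
wells at the Ct level; ΔΔCt subtracts the arithmetic mean ΔCt of the
calibrator samples (equivalently, the geometric mean of their expressions),
so calibrator expressions centre on 1 geometrically; expression = 2^−ΔΔCt.

## Synthetic experiments

The generator emulates the *geometry* of EdU-seq under HU, not its
biochemistry: flat Poisson background (default 10 reads/bin), origins as
triangular pileups (amplitude 800 reads at the peak, linear decay to zero
at ±`peak_halfwidth_bins` = 2 bins — HU confines nascent DNA near the
origin), an i.i.d. masked-bin fraction (default 5%), and non-overlapping
genes with log-normal lengths (default ln-mean 10, ln-SD 1 ≈ 22 kb median)
placed uniformly via gap splitting, so the chance a uniformly-chosen base
pair falls in a gene is proportional to gene length. Defaults: 2 × 50 Mb
chromosomes (10,000 bins), 30 constitutive + 30 induced origins, induced
fold 5. Counts are Poisson around the intensity field; bin-level Poisson is
a good approximation of read sampling at 10-kb resolution and moderate
depth. One top-level seed drives a single `numpy.random.Generator`; equal
seed and config give bit-identical output.

Constitutive origins add their amplitude to both libraries. Induced origins
add it to the treated library only, plus a *calibrated* residue to the
control library. The residue is not amplitude/fold: σ divides each track by
its own genome-wide SD, and the treated track — which carries the extra
induced signal — has the larger SD, so a naive amplitude/fold residue
deflates every ratio by s_control/s_treated (≈ 0.75 at the default
geometry) and a fold-2.5 origin could never cross the 2.0 class threshold.
Instead the generator solves, by fixed-point iteration on the expected SDs
(Poisson within-bin variance plus between-bin intensity variance), for the
residue that makes the *expected σ ratio* equal the requested fold. With
fold 1 the solution is exactly the full amplitude, making treated and
control identically distributed, as a null condition should be. The
`control_leak` override restores a fixed residue fraction for users who
want raw-amplitude semantics. The default fold is 5 rather than 4 because
ratio 4 sits exactly on the closed 2:1/4:1 class boundary, where sampling
noise would split a fold-4 origin's calls between classes.

Induced-origin placement: `induced_genic_bias=None` (default) places
origins uniformly over eligible bins — equivalently uniformly per mappable
base pair, which already hits long genes more often and is the placement
used for the gene-size property checks; a value in [0, 1] instead draws a
Bernoulli choice between fully-genic and non-genic bins. Origins keep a
minimum separation (default 10 bins) so kernels never overlap and peak
merging cannot fuse two planted origins.

Fibre tracks are base length (speed × label time / 2.59) plus Gaussian
measurement noise truncated at zero. Ct tables are built as
Ct = baseline − log2(expression) + Gaussian noise with the reference gene
at a fixed baseline in every sample.

### What the generator does not emulate

Replication-timing domains and any spatial autocorrelation of background;
mappability structure beyond an i.i.d. masked fraction; fragment-level
reads (the generator emits bin counts, not FASTQ); GC or copy-number bias;
overlapping genes and isoform structure; fork directionality. Passing
recovery tests therefore demonstrates the correctness of the binning, σ,
peak-calling, classification and annotation logic under the stated noise
model — not performance on real libraries, where background structure and
mappability would dominate the error budget.

## Numerical choices and degenerate inputs

Zero total counts or an all-equal count vector raise a degenerate-track
error rather than returning NaN σ. SD uses ddof = 1 throughout. Ratio
boundaries are closed as stated above and tie-breaks (plateau leftmost,
merge higher-then-leftmost, greedy closest-first matching with
first-set-then-second-set order) are deterministic; no randomness exists
outside the generator. bedGraph values are written with 4 decimals; all
file writes are atomic (temp + rename); reports hash their configuration
(output paths excluded) so reruns are byte-identical.

## Problem sizes

The default synthetic geometry (10,000 bins, 60 origins, ~2 × 10⁵ reads per
library) runs the full pipeline in about two seconds and gives planted peak
σ ≈ 10 with ratio noise around 8–10%, comfortably separating the classes;
the oracle-equivalence suites use up to 10,000-bin random tracks and a 1-Mb
per-bp annotation scan. These sizes were chosen so the complete test suite
and the acceptance script re-measure every claim in well under a minute
each while keeping all class margins ≥ 2 noise SDs.

## Known limitations

- The treated:control σ ratio is only meaningful when both libraries carry
  comparable total origin signal. A control library with *no* origin signal
  at all collapses to its Poisson floor: every control bin then sits near
  σ ≈ √background and all ratios compress toward a constant (~2 at the
  default geometry). Real paired libraries always share the constitutive
  origin complement, and synthetic configurations should too.
- Genome-wide SD normalisation assumes chromosomes are statistically
  exchangeable; per-chromosome scope is available but divides by noisier
  SD estimates on small chromosomes.
- The Mann–Whitney normal approximation is used whenever either sample
  exceeds 8 observations; for samples of 9–20 the exact p can differ from
  the approximation by a few percent in the tails.
- Greedy origin matching is symmetric only up to its documented tie-break
  and is not an optimal bipartite assignment; at the default tolerance of
  1 bin the difference never arises in practice.
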