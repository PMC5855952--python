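# Methods

## Reactivity model

SHAPE-MaP reads out chemical adducts as mutations. The package models the
per-nucleotide mutation probability in the treated (1M7) channel as

    p_i = clamp(background_rate + mod_detection_scale · reactivity_i, 0, 1)

and as `background_rate` alone in the untreated (DMSO) channel. The
estimator is the standard background-corrected rate difference

    raw_reactivity_i = events_treated_i / depth_treated_i
                     − events_untreated_i / depth_untreated_i

computed only where both channels reach `min_depth` (default 1000, the
community working value for MaP libraries). Negative corrected values are
genuine background fluctuation and are kept (clipping to zero is opt-in).
Profiles are scaled to normalized SHAPE units by one positive multiplier
from the 2%/8% box rule: sort the usable values descending, drop the top
2 % (at least one value), and divide by the mean of the next 8 % (at
least one value). An `external_reference` mode computes the same
statistic from a supplied reference distribution — the role played by a
deeply probed full-length transcript — and applies it unchanged.
Normalization refuses to run on fewer than 20 usable positions. Both the
integer band sizes use floor-with-minimum-one; at the 50–200-position
profile sizes this package targets the choice only matters at the
boundary and is covered by the brute-force oracle test.

## Allele sorting

A read pair is assigned by the base observed at the variant position: one
covering mate decides; two agreeing mates decide; two disagreeing mates,
a deletion over the site, a base matching neither allele, or a base below
`min_base_quality` (default Q20) put the pair in `other`; pairs with no
covering mate are `unassigned`. `other` and `unassigned` pairs are
excluded from both allele pools — ambiguous evidence is discarded rather
than rescued. Under a symmetric substitution error `e`, a spanning read
is misassigned only when the error converts the site to the one other
allelic base, so the misassignment rate is `e/3`; the acceptance suite
verifies this law at depth 10⁵. The variant position itself is masked in
downstream profiles: its apparent "signal" is the allele difference, not
a SHAPE adduct.

## Comparison features and classification

Two allele profiles are compared over a window of ±50 nt around the
variant (within the 50–150-nt read-coverage range that allele-specific
data supports), excluding the variant site and any position missing in
either profile; fewer than 10 shared positions is an error. The feature
vector holds Pearson r, Spearman ρ, the structural disruption coefficient
eSDC = (1 − r)·√n, the number of compared positions, the maximum
|Δreactivity|, the count and longest run of positions with |Δ| ≥ 0.5
normalized units (half the typical normalized dynamic range), and the
signed Δ area before and after the variant.

Two classifiers share this interface. The **threshold rule** maps eSDC to
a score `1 − exp(−eSDC/5)` ∈ [0, 1) and calls riboSNitch at score ≥
0.079. That default threshold is the 90th percentile of the synthetic
within-sample null — ratiometric 75/25 splits of a single simulated tube
at depth 3000 — computed by `calibrate_default_threshold()`, so the null
false-call rate of the within-sample design is 10 % by construction. The
**random forest** (`train_on_synthetic`) is trained on simulated
changer/nonchanger comparisons over an effect grid (1.0, 1.5, 2.0
normalized units over a 15-nt block) and a replicate-noise grid (log-SD
0.05–0.3); it fills the role of an expert-trained profile-comparison
classifier with a fully synthetic, reproducible training set. Identical
profiles are nonchangers under every model by rule.

## Design evaluation

`evaluate_designs` scores one variant panel (half changers with a planted
block effect, half nonchangers) under both experimental designs:

* **between-replicate** — each allele probed in its own tube: each
  tube's ground truth is perturbed by independent per-position lognormal
  replicate noise before observation, and each tube sequences at full
  depth;
* **within-sample** — both alleles in one tube: a single shared tube
  factor, no between-allele replicate noise, with the depth split
  75:25 between alleles.

Observation in this evaluation is count-level: per-position binomial
mutation events at the stated depth, which is exactly the sampling
marginal of the read-level simulator when sorting is error-free, and two
orders of magnitude faster. Both designs are scored identically and
summarized by ROC/AUC (trapezoid over descending score thresholds, tied
scores sharing a point; equal to the Mann–Whitney statistic with ties
counted ½).

The qualitative result — within-sample AUC ≥ between-replicate AUC
whenever replicate noise is nonzero — holds robustly. The *magnitude* of
the gap under this noise model is modest: with iid fixed-σ lognormal
noise, the null correlation over ~100 window positions concentrates
tightly, so a fixed planted effect separates well in both designs. Real
replicate noise is heterogeneous across library preparations and real
effect sizes vary, which is what drives the large gaps seen in practice;
reproducing that would require a noise model with between-pair variance
that `perturb_replicate`'s single-σ definition deliberately does not
have. This is a known limitation of the generator, stated here so that
passing tests are not over-read: they demonstrate the direction and the
machinery, not field-scale effect sizes.

## Synthetic data: what it does and does not emulate

`mapsim` emulates the parts of MaP chemistry the analysis depends on:
reactivity-dependent mutation probabilities, background/sequencing error
folded into one rate (the analysis only ever uses channel differences),
two-allele mixtures at a stated fraction (default 0.75 alternate — the
mutagenized template dominates and wild-type makes up the rest), uniform
fragment placement with Gaussian fragment lengths, and mutations drawn
per molecule so overlapping mates share adducts. Ground-truth
reactivities draw from Gamma(2, 0.6) at unpaired and Gamma(0.6, 0.1) at
paired positions (means 1.2 and 0.06 normalized units), reproducing the
low-median-reactivity signature of structured regions. Not modeled:
quality-score variation (one constant Q), PCR duplicates, GC bias,
indels (substitution-only by default), ligation/primer artifacts, and
position-correlated noise. Truth labels (per-fragment allele, ground
truth reactivity) live in sidecar TSVs, never in the SAM the pipeline
reads.

## Window analytics

Sliding statistics use centered windows; a position whose window runs off
the transcript is undefined rather than computed on a shrunken window, so
a track's support is constant. The sliding median (default 41 nt, even
sizes rounded up) ignores missing values but requires ≥50 % usable
positions; windowed Pearson correlation (default scales 10–50 nt)
requires ≥5 pairwise-complete positions and non-constant windows.
Similar/dissimilar regions are positions beyond mean ± 0.75·SD of the
defined track values, merged into maximal runs — a scale-free rule.
Bootstrap enrichment re-places the region intervals uniformly at random
without overlap (a stars-and-bars construction preserving count and
lengths) and reports `p = (1 + #{null ≥ obs}) / (n_boot + 1)`. The
empirical p-value is discrete and conservative under heavy ties, so its
uniformity under the null is tested at problem sizes where the overlap
count is well spread.

## Ensemble comparison

Structure samples for the two alleles (dot-bracket, produced by an
external SHAPE-directed folding engine) are pooled and clustered in one
shared space so cluster populations are directly comparable between
alleles. The metric is base-pair distance (symmetric difference of pair
sets — a true metric, property-tested); clustering is PAM k-medoids with
the deterministic BUILD initialization and best-improvement SWAP, so
results are reproducible without a seed; `k` is chosen by mean silhouette
over 2–6 unless fixed. Each cluster is represented by its medoid
structure, and the allele-induced shift is summarized per cluster
(fraction_alt − fraction_ref) and overall by the total-variation distance
½·Σ|Δ| ∈ [0, 1]. Visualization uses classical (Torgerson) MDS with
negative eigenvalues clipped; the Spearman correlation between embedded
and original distances is reported as an embedding diagnostic.

## qRT-PCR relative expression

ΔCT = CT_target − CT_control per replicate; replicates more than one
cycle from their median are dropped (and logged) before averaging. The
default readout is the exponential convention
`2^(−ΔCT_dox) / 2^(−ΔCT_untreated)`; a `--literal-formula` flag computes
`(−ΔCT_dox)² / (−ΔCT_untreated)²` instead. The squared form appears in
some write-ups but squares a negative base, which cannot represent an
expression ratio in general; both are implemented and the exponential
form is the default.

## Numerical and interface conventions

Coordinates are 0-based half-open internally and in BED/bedGraph I/O;
SAM and `.map` output are 1-based per their standards. U is mapped to T
for read-level work. Missing values are NaN internally and −999 in
`.map` files. Constant comparison windows fall back to r = 1 for
identical vectors and r = 0 otherwise. All stochastic operations take
explicit seeds; same seed means byte-identical SAM, model, and report
files. Problem sizes in the test and acceptance runs (transcripts of
60–200 nt, depths 3–100 k, 20-seed design evaluation) were chosen as the
smallest sizes at which the binomial and correlation statistics being
tested are well resolved.
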