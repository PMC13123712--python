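# Methods

This note documents the statistical procedures, their assumptions, the
defaults that matter, and the design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Preprocessing

**Contaminant removal.** Two scores per taxon, with removal only on
joint evidence (both-modes intersection, threshold 0.1):

- *Frequency mode.* Reagent contamination contributes a roughly fixed
  number of molecules per reaction, so a contaminant's relative
  abundance scales like 1/(sample DNA concentration). Over the samples
  where the taxon is present, we compare the residual sum of squares of
  log(relative abundance) = log(1/dna_conc) + b (slope fixed at 1,
  intercept free) against an intercept-only fit, scoring the ratio on
  an F(n−1, n−1) scale, one-sided in favor of the contaminant model.
  This is a deliberately simplified score with the same decision
  structure as the established tool's; the tool's exact internals are
  not reproduced (they are not the contribution here — the removal rule
  is).
- *Prevalence mode.* A 2×2 presence/absence table (taxon present ×
  negative-control vs true sample), one-sided chi-squared (no
  continuity correction) favoring higher prevalence in negatives.
  Degenerate margins give p = 1.

Taxa with lineage kingdom *Eukaryota*, order *Chloroplast(s)*, or
family *Mitochondria* are removed regardless of the scores. Taxa
flagged by a single mode are always retained.

**Pruning.** Samples under 1,000 reads are dropped first; then taxa
whose per-sample proportion never reaches 1% in any retained sample.
The "max per sample" reading of the proportion filter is a documented
choice: a dataset-wide reading would annihilate typical tables, and it
mirrors the detection-threshold style used for the core-microbiota
definition. Pruning is idempotent.

**Agglomeration.** Counts are summed over taxa sharing the lineage
prefix down to the requested rank (genus by default); taxa unassigned
at that rank pool into `unclassified_<nearest assigned parent>`.

## Compositional scale

Zeros are replaced multiplicatively: each zero in sample *i* becomes
δ_i = 0.65·1/(N_i + 1) with N_i the sample's total count, and nonzero
parts are rescaled so the row still closes to 1 (a warning is emitted
if δ_i is not below the sample's smallest nonzero proportion). The CLR
transform is log(x_j) minus the row's mean log. Ordination is PCA of
the column-centered CLR matrix via SVD — mathematically identical to
principal coordinates on Aitchison distances but yielding taxon
loadings; Euclidean distances between full score rows equal the
Aitchison distances to 1e-8. Group separation is tested by factor
fitting on the first two components (the plotted plane; whether more
components should enter is an open choice — 2-D is the documented one):
r² = 1 − SS_within/SS_total of the 2-D scores, with a seeded label
permutation p-value, 999 permutations by default.

## Diversity

Shannon H in nats over observed taxa; Pielou J = H/ln(richness),
undefined (NA) for single-taxon samples. Core membership requires
proportion strictly above the detection threshold (default 1%) in at
least 50% of samples; a detection-grid variant reports the prevalence
fraction at each threshold. Group comparisons run a Shapiro–Wilk gate
at α = 0.05 per group (on paired differences when paired) and fall back
from the t-test to the rank test on rejection; the gate can be forced
either way because published analyses are inconsistent about which test
produced which p-value.

## Co-occurrence networks, Δρ, cohesion

Networks are Spearman matrices (average ranks for ties) over the
top-N genera by mean relative abundance (N = 30; ties broken
lexicographically), computed on relative abundances — a CLR-scale
switch exists because the choice of scale is not settled; rank-based
correlation makes the monotone-transform question moot within a scale.
BH adjustment runs over the upper triangle of one cohort's matrix only;
pairs involving a zero-variance taxon are excluded from the family and
counted. Display order is average-linkage clustering on 1 − ρ.

Δρ is the per-pair difference of two cohorts' matrices on their shared
taxa; |ρ| distributions are compared by rank-sum, the Δρ distribution
against zero by signed-rank. Connectedness of a genus is the mean of
its positive (resp. negative) off-diagonal correlations (0 when empty);
cohesion of a sample is the abundance-weighted sum of connectedness
over the network taxa after re-closing the sample to that taxon set.
No null-model correction is applied — the quantities' published usage
names only their construction and ranges, so the simplest construction
consistent with those ranges (κ⁺ ∈ [0,1], κ⁻ ∈ [−1,0], likewise
cohesion) is used.

## Monte-Carlo CLR differential abundance

For each sample, n_mc = 128 proportion vectors are drawn from
Dirichlet(counts + 0.5) and CLR-transformed (fewer than 16 instances is
refused — the expected adjusted p would be unusably noisy). Per
instance, a two-sided rank-sum test per taxon (signed-rank available
for paired designs; rank-sum is the default even for pre/post because
that is how the printed analysis was run), BH across taxa; the reported
q is the mean adjusted p over instances (BH is never applied to
averaged p-values). The effect size pools, across instances,
min(group sizes) random pairings of between-group CLR differences
scaled by the larger of the two within-group dispersions, and takes the
median. Its null sampling sd at n = 20/group is roughly 0.15 — single
null taxa can drift past |0.3|; the dual rule (|effect| > 0.5 AND
q ≤ 0.001, both strict) is what keeps the false-call rate at zero in
the null experiments. `median_clr_diff` is the median of the same
pooled between-group differences, so it shares the effect's sign by
construction. The marker-correlation arm computes per-instance Spearman
ρ of each taxon's CLR against a continuous marker with a t-approximate
two-sided p, BH across taxa, reporting means over instances.

## Microbe–immune association testing

Genera detected (proportion > 0) in under 30% of samples are excluded.
The spline arm regresses one taxon's CLR values (the mean over MC
instances) on one marker density using a basis of the standardized
marker and an orthogonalized quadratic term (basis dimension 3 with the
intercept). Both directions carry separate shrinkage penalties whose
two smoothing parameters jointly minimize the restricted likelihood —
the double-penalty construction behind automatic smooth-term selection —
so an unrelated smooth is penalized to ~0 edf, a linear signal sits at
edf ≈ 1, and edf never exceeds 2. The reported p-value is the exact
F-test of the unpenalized 2-df basis against intercept-only: exactly
calibrated under Gaussian noise, at the price of not reflecting the
penalization (approximate p-values for penalized fits are themselves a
compromise; exact calibration was preferred because the concordance
rule consumes this p through an FDR family). Fits are invariant to
affine rescaling of the marker.

Concordance BH-adjusts the spline arm's p-values across the full
taxon × marker grid; the correlation arm contributes its expected
adjusted p from the MC pipeline (re-adjusting an already-adjusted
expectation would be incoherent, so the arm's own family definition —
taxa within marker, per instance — stands). A pair is reported only if
both adjusted values are ≤ 0.05 and, by default, the spline's
end-to-end trend sign agrees with the correlation sign
(`require_sign_agreement` can disable the sign check; it exists to
prevent reporting a pair "significant" in opposite directions).

## Immune densities and demographics

Densities are counts per mm² of tissue. Epidermis vs dermis uses paired
signed-rank per (marker, aspect), dropping and logging participants
missing a layer; elective vs pathological phimosis uses rank-sum per
(marker, aspect, layer). BH runs over all markers × compartments within
one comparison type — the widest within-comparison family, the
conservative choice where the family is not pinned down.

Age differences use Kruskal–Wallis. Ethnicity uses an r×c Fisher exact
test implemented as depth-first enumeration over all tables with the
observed margins, summing the probabilities of tables no more likely
than the observed one (tolerance 1e-7 on log-probability ties, as in
standard implementations). When the candidate space exceeds ~5×10⁶
tables, a seeded Monte-Carlo over fixed-margin tables (≥ 10⁵ draws,
permutation sampling) is used instead and the MC standard error is
reported. The enumeration was written in-house because the installed
scipy's r×c path is randomized (its p changes under row/column
permutation); it is validated against R's `fisher.test` in spirit and
against scipy's exact 2×2 path in the test suite.

## Synthetic cohorts

The generator is logistic-normal-multinomial: latent
z ~ MVN(μ, Σ) per sample, proportions = softmax(z), counts ~
Multinomial(depth, proportions), depth ~ round(lognormal), floored at
1. Σ has unit variances, `within_block_cov` inside a guild block,
`between_block_cov` across blocks, 0 elsewhere, with eigenvalue
clipping at 1e-10 (nearest-PSD projection) so arbitrary block settings
remain usable. This is the simplest standard compositional model in
which block covariance plants guild structure while multinomial
sampling preserves count over-dispersion.

Defaults encode the study conditions the pipeline targets:

- `pediatric-like`: 30 genera, no blocks (diffuse correlations), depth
  scale ~47,700 reads (log-sd 0.4 — the depth *distributions* of the
  real cohorts are unpublished beyond their means, so only the order of
  magnitude is calibrated); indications sampled at roughly the cohort's
  31/27/42% elective/non-elective/phimosis split; ages uniform on
  0.5–17.5 years.
- `adult-like`: two 12-genus blocks — a gram-positive skin guild and an
  anaerobe guild — with within-block covariance 0.6 and between-block
  −0.4, depth scale ~190,600 reads.

Paired designs share each subject's latent z between timepoints and add
a configurable log-abundance shift at "post" before a fresh multinomial
draw. Immune densities are exp(log baseline + Σ links sign·strength·CLR
+ N(0, 0.3)) in the linked compartment (inner dermis by default), with
layer-specific baselines at the scale observed in foreskin tissue
(macrophages dominant in dermis, Langerhans cells in epidermis) and a
multiplicative phimosis-group factor on configured markers in the
dermis. Contaminant spiking appends reagent taxa that dominate negative
controls (~99.5% of reads) while contaminating each true sample with
probability 1/2 at a proportion ∝ 1/dna_conc — sporadic presence is
what gives the prevalence mode its signal, and the concentration
coupling is the frequency mode's; an uncoupled switch provides the
frequency-mode null.

What the generator does **not** emulate: taxonomic assignment error,
chimeras, depth–composition dependence, overdispersion beyond the
logistic-normal (no zero-inflation), subject-level covariate structure
(age effects on composition), or spatial correlation between immune
compartments. Passing recovery tests therefore demonstrate that the
pipeline detects the planted statistical structures at realistic sizes
and noise — not that real cohorts satisfy the generator's assumptions.

## Experiment sizes and numerical choices

Recovery experiments (in `guildshift.experiments`, run by both the test
suite and the acceptance script) use 10 seeds each at the cohort sizes
the analyses target: n = 60/cohort for the network contrast, 40 pairs
for differential abundance (n_mc = 128), 50 samples for the dual-arm
associations; null calibrations use 200 replicates per family (400 for
the BH any-discovery indicator, which is a single Bernoulli per
replicate and needs the extra replicates for a stable rate). Per-seed
child seeds are spawned through `SeedSequence` so experiments do not
share streams across base seeds; every random operation in the package
takes an explicit seed and is bit-reproducible.

Tie-breaking and degenerate inputs: taxon rankings break ties
lexicographically; signed-rank on all-zero differences returns p = 1;
zero-variance taxa yield NA correlations excluded from BH families;
samples with no abundance on the network taxa get NA cohesion with a
warning; enum labels are lower-cased on ingest; TSVs use `NA` for
missing and round-trip floats to 12 significant digits.

## Known limitations

- The spline arm's p-value ignores the penalization (exact unpenalized
  F-test); edf and adjusted R² come from the penalized fit. Curvature
  beyond a quadratic within the 3-dimensional basis is invisible.
- The effect-size estimator's random-pairing approximation bounds cost
  but adds Monte-Carlo noise (~0.05 at n_mc = 128) on top of its
  sampling spread.
- The frequency-mode contaminant score assumes presence-conditional
  log-linearity and needs ≥ 3 presence samples with known DNA
  concentration; taxa below that give NA and are never flagged.
- Cohesion/connectedness omit any null-model correction; values are
  comparable within this package, not with null-corrected variants.
- The r×c Fisher enumeration is exponential in table size; large tables
  silently switch to seeded Monte-Carlo (the switch and its standard
  error are reported in the result).
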