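# Methods

This note documents the models implemented in `sigdyn`, the defaults they
ship with, and what the synthetic-data experiments do and do not
demonstrate.

## Signature refitting

Each sample's SBS-96 (or ID-83) spectrum is normalized and regressed on a
reference matrix by non-negative least squares. The weights are normalized
to fractions, every fraction below the confidence threshold (default 5%) is
set to exactly zero, and the surviving signatures are refit and
renormalized. The residual reported per sample is the Euclidean distance
between the observed and reconstructed normalized spectra. This NNLS +
threshold + restricted-refit scheme keeps the contract of constrained
refitting with small-signature pruning while being directly checkable
against a grid-search oracle on the weight simplex; the tests do exactly
that for two-signature mixtures at 0.01 resolution. The 5% rule reflects
caller-concordance arguments: below that prevalence, contribution estimates
are unreliable, so they are treated as absent.

Deficiency phenotypes are thresholded-exposure rules, all strict at 5%:
HR deficiency requires SBS3, SBS8, ID6 and ID8 simultaneously above 5%;
colibactin exposure requires SBS41 and ID18; MMR deficiency requires SBS44.
The conjunction is configurable (`DeficiencyRules`) because reasonable
analysts differ on whether ID6 *and* ID8, or either, should be required;
the default is the conservative all-of rule.

## Bundled reference signatures

The package ships *synthetic* signature profiles under the COSMIC names its
rules refer to (SBS1, SBS2, SBS3, SBS5, SBS8, SBS17a/b, SBS18, SBS35,
SBS40, SBS41, SBS44; ID1, ID2, ID6, ID8, ID18). Each is a caricature with
the hallmark peak structure of the process it stands in for (SBS17b mass on
N[T>G]T, SBS1 on N[C>T]G, ID6 on microhomology deletions, ...) plus seeded
Dirichlet jitter, constructed so that pairwise cosine similarities stay
low (max ≈ 0.53). Real analyses must substitute the licensed COSMIC
matrices via `read_signature_matrix`. Indel profiles place mass only on
channels realizable on an i.i.d. genome; long-repeat channels
(e.g. 5-unit tandem counts) are intentionally unused by the generator.

## Clonality and timing

CCF and multiplicity follow the standard purity/copy-number inversion
(README formula). CCFs are capped at 1.25 with a flag. "Purity-corrected
VAF" is interpreted as CCF with per-mutation multiplicity — the only
correction that puts mutations from different copy-number states on a
comparable scale — and the dip test runs on those CCFs.

**Dip test.** The dip statistic (sup-norm distance from the ECDF to the
nearest unimodal CDF) is computed with the iterative greatest-convex-
minorant / least-concave-majorant squeeze, in count units with a final
division by 2n. The implementation is validated against an independent
linear-programming oracle that, for every candidate mode knot, finds the
best piecewise-linear unimodal CDF under the ECDF sandwich constraints;
agreement is exact to 1e-9 on random small samples with distinct values
(for tied values the LP relaxation is not a valid oracle — a unimodal CDF
may jump only at its mode). p-values are Monte Carlo: the observed dip is
ranked against `n_ref` (default 2000) dips of uniform samples of the same
size, p = (1+k)/(1+n_ref), with ties counted as exceedances. Null tables
are cached per (n, n_ref, seed). Uniform samples are used both as the
reference and in the type-I calibration test, where the rejection rate at
α = 0.05 is exact by construction up to binomial noise; for strongly
unimodal data (e.g. Gaussian) the test is conservative, as is standard for
the dip.

**Subclone decomposition.** Samples with dip p < 0.05 are decomposed with
a two-component 1-D Gaussian mixture (sklearn EM: tolerance 1e-6, ≤ 500
iterations, variance floor 1e-4, initialized from a median split). The
component with mean nearer 1 is clonal; mutations with posterior > 0.5 for
the other component are subclonal (ties resolve clonal). A fit is
degenerate — and the sample reclassified fully clonal — when a weight falls
below 1%, the means coincide, or the subclonal mean exceeds 0.8. The last
guard exists because deterministic integer multiplicity assignment in
n_major ≥ 2 segments carves the clonal CCF cloud into artifact modes
hugging 1 (observed at 0.94/1.08 on a tetraploid test sample); without the
guard those modes masquerade as subclones and corrupt timing fractions. The
cost is blindness to genuine subclones above CCF 0.8, which are in any case
hardly distinguishable from clonal noise at 50× depth.

**Timing.** Clonal mutations in segments with n_major ≥ 2 are
`clonal_early` when m ≥ 2 and `clonal_late` when m = 1; in unamplified
segments timing is uninformative (`clonal_other`). Whole-genome doubling is
called when more than half the genome has n_major ≥ 2 and ploidy > 2.9.
Point estimates with binomial clamping replace bootstrapped probabilistic
assignment; at ≥ 50× depth the deterministic rules recover planted
early/late fractions within a few percent (tested at 10%).

## Nucleosome periodicity

Mutations within ±72 bp (zoom-in) or ±1000 bp (zoom-out) of a dyad are
stacked at signed offsets; a mutation near several dyads contributes at
each. The null relocates each stacked mutation uniformly among positions
in the stacked windows sharing its pyrimidine-oriented pentamer, conserving
the pentamer multiset exactly; the expected profile is the mean over
`n_rand` randomizations (mean chosen for unbiasedness). The relative
increase r(x) is mean-centred (suppressing the zero-frequency term);
zoom-out profiles are additionally detrended with a 50-bp moving average to
remove linker-scale trends. The periodogram is an explicit-sum DTFT over
periods 5–50 bp in 0.01 bp steps — a plain DFT on 145 offsets cannot
separate 10.3 from 10.15 bp, so oversampling is essential. SNR is peak
power over the median power of the band excluding the peak ± 0.5 bp
(median for robustness to secondary peaks). The empirical p pushes every
randomized set through the identical chain, each against the leave-one-out
mean of the other randomizations, making observed and randomized SNRs
exchangeable under the null; calibration tests confirm uniform p-values
under uniform mutagenesis (KS). Ties count as exceedances:
p = (1+k)/(1+n_rand).

Strand conventions are fixed and documented rather than inferred: a
mutation is *transcribed-strand* when its pyrimidine lies opposite the
gene's coding strand; in a right-travelling replication domain a pyrimidine
on "+" is labelled *lagging* (roles swap in left-travelling domains).
Biases are log2 count ratios (+0.5 continuity correction at zero counts)
with two-sided binomial tests.

## DDR, CIN and proliferation

Gene copy-number calls use the segment with maximal overlap: AMP when the
total copy number is ≥ 2× ploidy, DEL when ≤ ploidy/2, LOH when the minor
allele is 0 (so a hemizygous deletion is both DEL and LOH, and AMP/DEL are
mutually exclusive for any positive ploidy). SNV/indel hits require a
consequence from the non-synonymous allow-list (missense, nonsense,
stop gained/lost, frameshift, in-frame indels, initiator/terminal codon,
UTR and TF-binding-site variants); annotation is consumed, never computed.
A pathway is hit when any member gene is. The CIN score counts segments
with total copy number different from the *rounded ploidy* spanning > 5%
of their chromosome, Z-scored across the cohort — ploidy-relative rather
than diploid-relative, because a WGD genome would otherwise score every
segment as abnormal. Proliferation is 1 − QS with QS the arithmetic mean
of cohort Z-scores of G0-arrest markers (combination configurable).

## Dynamics and classification

Subclonal shifts are Δ = subclonal − clonal exposure fractions per sample
and signature, computed from raw (unthresholded) per-compartment refits by
default, with a 50-mutation floor per compartment below which a sample is
masked (exposure estimates destabilize under that). Group comparisons are
two-sided Wilcoxon (rank-sum unpaired, signed-rank paired) with optional
Benjamini-Hochberg adjustment; exactness is verified against full
enumeration for small groups. Dominance labels use a strict majority of
summed exposures.

The stage classifier follows the study protocol: stratified 70/30
discovery/validation split, hyperparameters by repeated stratified 5-fold
CV (default 100 repeats; tests use fewer), held-out AUC (binary, or macro
one-vs-rest for three stages), and permutation importances on the held-out
set — a model-agnostic replacement for Shapley values with the same ranking
intent. Learners: sklearn gradient boosting, random forest, multinomial
logistic regression, pluggable behind one train/predict contract.

## Synthetic cohort generator

The generator defines the study conditions: i.i.d. bases at GC 0.4 (no
download, every context realizable), dyads every 197 bp (147 bp core +
50 bp linker) with ±10 bp jitter, genes tiling ~50% of the genome on
alternating strands, replication domains alternating direction. Default
sequencing depth is 50× (Poisson-distributed per site, binomial allele
sampling conditioned on ≥ 1 alt read, since an unobserved variant is never
called); about half of samples carry one subclone (CCF uniform in 0.3–0.7),
matching the ~51% subclonality prevalence the pipeline is meant to face.
Stage exposure templates keep SBS17a/b dominant throughout, add APOBEC
(SBS2) and SBS41 in primaries, raise SBS17b in metastases, and shift
SBS17a/b down by 0.1 each in subclones with the slack moved to ageing
signatures. Periodic positional planting uses a cosine acceptance weight
1 + a·cos(2πd/T) within ±73 bp of dyads; the defaults are T = 10.3 bp for
bulk SNVs and T = 10.15 bp for SBS17b, with amplitude 0.6. Indels are
sampled channel-first: homopolymer channels from a run-length index,
longer repeat/microhomology channels by rejection probing with the ID-83
classifier itself as the acceptance oracle; a channel with no realizable
site raises a `SimulationError` naming it.

What the generator does *not* emulate: mapping and sequencing error,
germline contamination, FFPE artefacts, real human chromatin maps, clonal
phylogenies deeper than two populations, dysplasia grades within Barrett
samples. Passing tests therefore demonstrate correctness of the inference
chain under its own model assumptions — recovery of planted truths — not
performance on real tumour genomes.

## Problem sizes used in the checks

The bundled experiments run on 0.4–1 Mb genomes: periodicity recovery uses
~20,000 stacked mutations with 200 randomizations; exposure recovery uses
50 samples × 5,000 SNVs; null calibration uses 200 replicates × 200
randomizations; shift recovery uses 30 two-clone samples × 4,000 SNVs.
These sizes give the statistics enough power that the stated tolerances
(±0.2 bp on the period, MAE < 0.05 on exposures, ±0.05 on the median
shift) are comfortably inside the estimators' sampling noise.
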