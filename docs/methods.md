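# Methods

This note documents the models, conventions and design choices behind each
stage of the pipeline, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer would want recorded.

## Linkage disequilibrium

LD is computed from *phased* haplotypes only; there is no EM phasing of
unphased genotypes. This keeps r² an exact function of the haplotype counts
(and hence exactly testable against the squared Pearson correlation of the
0/1 allele columns) at the cost of requiring a phased reference panel, which
is how such candidate sets are built in practice. Missing genotypes are an
error rather than silently dropped rows — dropping them would bias frequency
and haplotype estimates invisibly. Monomorphic sites raise instead of
returning NaN so no caller can accidentally rank an undefined pair.

`select_proxies` includes the index SNP itself (r² = 1) whenever the
threshold admits it. The 11-variant candidate set of the default scenario
therefore means the index plus ten proxies at r² ≥ 0.7; the count convention
is explicit here because published counts of "variants meeting an LD
threshold" rarely state it. Ties in the proxy ranking are broken by
ascending genomic position for determinism.

The r² denominator is evaluated as `(p_a(1−p_a)) · (p_b(1−p_b))` — grouped
per site — so that `r2(a,b) == r2(b,a)` holds to the last bit, not merely to
rounding.

## Annotation overlap and prioritization

Peak files are BED-style 0-based half-open; variants are VCF-style 1-based.
The conversion lives in exactly one place (`variant_overlaps_track`:
overlap iff `start ≤ pos−1 < end`), because this off-by-one is the classic
failure mode of such pipelines. Chromosome-name dialects ("10" vs "chr10")
are normalized by stripping the prefix on comparison. Peaks are unstranded.

Point-in-peak lookup uses a binary search over starts plus a prefix maximum
of ends (correct even for nested peaks); tests assert equality with a
brute-force all-pairs scan.

"Overlaps chromatin signals" is operationalized as: candidate iff the
variant has ≥ 1 open-chromatin (DNase or FAIRE) peak hit. Histone marks and
TF ChIP peaks contribute to the ranking (open-chromatin count, then histone,
then TF ChIP, then position) but not to candidacy. This matches the
prioritization funnel the pipeline mirrors, where both selected variants sat
in DNase peaks and the other annotations served as corroborating evidence.

## Motif model

PFMs are parsed from JASPAR text in both the bracketed (`A [ 1 2 3 ]`) and
bare dialects, with labeled rows accepted in any order. The PWM is the
standard log₂-odds matrix with the pseudocount distributed by the
background:

    logodds[b][j] = log2( (counts[b][j] + pc·bg[b]) / (colsum_j + pc) / bg[b] )

Defaults: uniform background (0.25 each), pseudocount 1.0 — the
JASPAR-browser convention; both are arguments. The relative score
`(score − min) / (max − min)` is 1 exactly on the consensus and 0 on the
anti-consensus. Scanning covers both strands (reverse-strand windows are
scored on the reverse complement and reported at their original-sequence
offset); best-hit ties resolve to the + strand, then the smallest offset.
Ambiguity codes are rejected: probes are fully specified sequences.

A window "contains the consensus core" when its relative score reaches a
threshold, default 0.8 — a conventional PWM-match cutoff, exposed as a
parameter since no single value is canonical. The allele-effect call is
*created* when only the alternate allele's best hit clears the threshold,
*disrupted* in the mirror case, *neutral* otherwise; the score delta is
antisymmetric under allele swap by construction.

### The bundled forkhead-core matrix

The repository ships one synthetic PFM (`foxa_core_synthetic.jaspar`,
consensus TGTTTAC, L = 7) rather than a database matrix, so that tests do
not depend on an external database version. Its shape is deliberate: the
column at core position 3 — the position a risk allele can supply — is
fully constrained (18/0/0/0) while the other columns are 12/2/2/2. With
seven equally informative columns, any single mismatch would score
6/7 ≈ 0.86 relative and *every* point substitution would still "match" at a
0.8 threshold; concentrating information in the SNP-position column makes a
substitution there decisive (relative score 0.70) while single mismatches
elsewhere remain tolerated. This mirrors real forkhead PWMs, whose central
TGTTTAC core positions carry most of the information content. Loaders for
real JASPAR files are first-class; numeric scores will of course be
matrix-version-dependent, and only the qualitative created-by-risk-allele
call is portable.

In-silico PCR is exact-match only (no mismatch tolerance or thermodynamics):
it finds forward-primer sites and downstream reverse-complement
reverse-primer sites and reports end-to-end product lengths, primers
included. No product is an empty list, not an error.

## Reporter statistics

Per well, normalized activity = firefly / Renilla; per clone, fold change =
mean of the clone's replicate wells ÷ mean of the empty-vector wells. The
experimental unit is the **clone** (an independently isolated plasmid), not
the well: duplicate wells of one clone share the preparation and are not
independent. A `unit="well"` option exists for sensitivity analysis, as does
a log-scale option; defaults are clone-level on the linear fold-change
scale, matching how such assays are usually presented. The test is
two-sided; Welch's form by default (`equal_var=True` switches to Student's).
Forward and reverse construct orientations are analyzed separately, never
pooled. Two-SNP haplotype constructs are compared holding the other SNP's
allele fixed (`haplotype_contrasts` builds exactly those pairs).

## ChIP-qPCR and expression

Fold enrichment = `2^(meanCt_IgG − meanCt_antibody)` at the same sample and
region, i.e. a perfect-doubling assumption at the ratio level; per-target
efficiency correction is available through fitted standard curves. When
input rows are present, both antibody and IgG are first expressed as
percent of input with a dilution-of-input correction (default fraction 5%);
the input term cancels algebraically in the ratio, and a test pins that
equivalence. Replicate Ct values are averaged arithmetically; replicate SD
above 0.5 cycles is flagged.

The genotype comparison is a **one-sided** Welch t-test whose direction must
be declared in configuration (e.g. `"CT>CC"`, from prior binding evidence
such as an EMSA); an unspecified direction is an error, which prevents
silent post-hoc sidedness. Identical groups return p = 0.5, the one-sided
null boundary.

Standard curves regress replicate-mean Ct on log₁₀ relative quantity over a
serial dilution (default 3-fold); efficiency E = 10^(−1/slope), warned
outside (1.6, 2.2), positive slopes rejected. Relative expression is
curve-based quantification (not ΔΔCt): each target converted through its own
curve, gene ÷ housekeeping, Ct outside the calibrated range warns about
extrapolation. Condition comparisons are two-sided Welch tests on the
normalized quantities. No multiple-testing correction is applied anywhere;
reports carry an `n_tests_run` column instead.

## Synthetic-data generators

Every generator is a pure function of (configuration, seed); fixed seeds
give byte-identical output files.

**Haplotypes.** A two-SNP haplotype table achieving an exact target r² is
constructed as `p_AB = p_A·p_B + sign·√(r²·p_A(1−p_A)·p_B(1−p_B))` with the
remaining cells fixed by the marginals; infeasible combinations raise with
the maximum attainable r². Panels condition each proxy on the index column.
The default *exact-count* mode rounds haplotype counts to integers (choosing
the rounding that lands nearest the target r²), so pipeline tests separate
logic bugs from sampling noise; *sampled* mode draws chromosomes from the
exact tables for statistical property tests. Background variants are
independent Bernoulli draws. The default panel size is 379 diploid samples
(758 chromosomes), the scale of a European reference panel; at that size
integer rounding perturbs r² by well under 0.01. Variants are spaced 2 kb
apart, comfortably wider than the default 400 bp peaks, and the peak
generator verifies its own plan (a peak accidentally covering an unplanned
variant is an error, not a silent change of truth).

**Scenario defaults.** The default scenario encodes the emulated study
design: index SNP plus ten proxies at r² ∈ [0.71, 0.95] (so 11 variants meet
the 0.7 threshold), two sub-threshold variants at r² 0.50 and 0.38 and five
background variants; DNase/FAIRE/histone/TF tracks covering two of the
eleven; the printed 21-bp probe pair; luciferase ratios 2.1 (832/13-like)
and 1.4 (MIN6-, HepG2-like); ChIP enrichments 7.2 (FOXA1) and 4.2 (FOXA2)
in T-carriers against 1.0 in CC homozygotes and at the control region, with
3 vs 2 samples per genotype; expression induction 1.8-fold with 5 samples
per condition.

**Noise models.** Luminescence noise is multiplicative log-normal
(positive support, CV-parameterized, mean 1), applied independently to each
firefly and each Renilla reading, plus an optional per-clone log-normal
random effect; defaults are 20% per-well CV and 10% clone CV in the
scenario, while the Monte-Carlo performance studies use per-well CV 20%
with the clone effect off — the plate-noise condition they state. Ct noise
is additive Gaussian (SD 0.2 cycles for ChIP, 0.15 for expression) on top of
a per-sample base Ct (SD 0.5), which cancels in within-sample ΔCt as it does
in real assays.

**What passing tests do not show.** The generators emulate the *designs*,
not the full messiness of real data: no genotyping error or phasing
switches, no LD decay with distance (each proxy is conditioned on the index
only), no correlated peak structure or signal-level variation, no plate
position effects, no PCR inhibition or efficiency drift. Recovery of the
configured truths therefore validates the estimators and their wiring, not
robustness to artifacts outside these noise models. Reproducing the
real-locus headline numbers (the specific 11-variant set, r² = 0.74 against
the real panel, the 2-of-11 overlap with ENCODE tracks) requires the
external reference panel and annotation tracks and is out of scope here.

## Monte-Carlo studies and problem sizes

The repeated-experiment studies (fold-ratio recovery and power at 500
experiments, type-I error at 10,000) use vectorized simulators that draw
from the same noise model and apply the same scipy Welch t-test (via its
`axis` argument) as the table-level functions; the table pipeline itself is
exercised in the same tests on full generated plates/tables. Sizes — 500
plates for recovery/power, 200 tables for ChIP recovery, 100 for expression,
10,000 reps for null rejection rates — were chosen so Monte-Carlo error is
small against the tolerances being checked (e.g. binomial SE ≈ 0.002 at
10,000 null reps) while the whole suite stays quick to run.

## Known limitations

* r² only; D′-based selection and multi-population LD are not implemented.
* Candidacy is binary peak overlap; no signal-level or chromatin-state
  scoring.
* The scanner is exhaustive (fine for probe-scale sequences and small
  candidate sets); there is no genome-scale indexed scanning.
* Exact-match PCR only; primers with SNPs or near-matches are not modelled.
* One antibody/IgG pairing per sample-region block; replicate-level
  mixed models are out of scope.
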