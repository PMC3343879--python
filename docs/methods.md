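# Methods

`hlafinemap` implements a fine-mapping workflow for the classical HLA
region in case/control cohorts, together with a KIR×HLA compound-genotype
analysis and a synthetic-cohort generator that supplies ground truth for
every stage. This note documents the models, the defaults and why they
were chosen, the numerical decisions, and what the synthetic data do and
do not establish about behaviour on real cohorts.

## Data model and filtering

Subjects carry two classical HLA allele calls per locus (A, B, C, DQA1,
DQB1, DRB1) in WHO nomenclature, at two-field ("four-digit") or one-field
("two-digit") resolution, plus sex, a cohort-of-origin label, ancestry
principal-component scores and an optional KIR3DS1 presence flag. Allele
calls arrive typed or imputed; imputation itself is out of scope.

Allele frequencies are computed over non-missing chromosomes only (two per
typed subject per locus), and the count of excluded chromosomes is logged.
The candidate-variant filter retains alleles whose **control-group**
frequency strictly exceeds the threshold (default 1%); cases are never
consulted, so the filter commutes with any permutation of case genotypes.
Boundary alleles at exactly the threshold are excluded. Two-digit analyses
are separate runs over names truncated at the first colon.

## Amino-acid dosages

The protein sequence of an HLA molecule is fully determined by its
four-digit allele, so each subject's residue content at an aligned
position is read off a positional residue table (1-based mature-protein
coordinates; the table's header row fixes the convention). The additive
dosage for a (locus, position, residue) column is the number of the
subject's two alleles carrying that residue; for complete calls the
dosages at a position sum to 2 across residues. Gap or indeterminate
symbols are treated as missing at that position, never as a residue
level. Residue columns are filtered by the same >1%-in-controls rule as
alleles, applied to the minor frequency min(f, 1−f) so near-fixed residues
are dropped too. Alleles with identical protein sequence collapse into
identical columns by construction.

The packaged alignment (`data/alignment_synthetic.tsv`) covers the ~45
alleles exercised in the tests. Residues at HLA-B position 80 (the
Bw4-80I / Bw4-80T / Bw6 epitope split: Ile/Thr vs Asn) and position 116
(the 116Y tapasin-independence marker) follow published epitope
definitions; other positions carry synthetic placeholder residues with
realistic level counts. A full IMGT-derived table in the same TSV format
can be supplied in its place for real analyses.

The Bw4/Bw6 classifier is a pure function of the residue at HLA-B
position 80. The B*35 Px/PY peptide-binding groups ship as a YAML
name→allele-list file (Px: B*35:02, B*35:03; PY: B*35:01); group
definitions must not overlap.

## Association testing

Single terms use additive logistic regression (dosage 0/1/2) with a Wald
test, adjusting for sex, cohort indicator columns and the leading ancestry
PCs (the number of PCs is a config value; the source analyses used 7 and
10 in their two GWAS cohorts). Conditioning is implemented by adding the
conditioned dosages as covariates. Fitting is Newton–Raphson via
statsmodels with relative tolerance 1e-10 and at most 100 iterations.
Aliased covariate or conditioning columns are dropped greedily (latest
first, the focal term protected) with a warning; a zero-variance focal
term is an error. Separation is flagged post hoc — non-convergence or
|log-OR| > 15 marks the result unstable and a ridge-stabilised IRLS
fallback (penalty 1e-3) keeps the estimate finite — rather than reporting
a spurious p-value.

Multi-residue positions get a single omnibus p-value: a likelihood-ratio
test of the model with k−1 residue dosages (one reference residue dropped)
against the covariates-only null, on k−1 degrees of freedom. For complete
calls the k dosage columns sum to the constant 2, so the statistic is
invariant to the choice of reference. Wald tests were chosen for single
terms and the LRT for the omnibus to match standard GWAS-toolchain output.
Positions with gap states are handled by the missing-data rule above, so
gaps never contribute a degree of freedom.

Scans rank results by ascending p with deterministic tie-breaks
(descending |beta|, then term name); per-term failures are logged and the
scan continues.

## Stepwise selection

Forward selection from an empty model (or a forced seed term such as the
strongest single allele): at each step every unselected candidate is
tested conditional on all selected terms; the smallest conditional Wald p
enters if it beats the threshold. There is no backward elimination. The
stopping thresholds ship as constants — 0.0006 (0.05/88 class I+II
candidate alleles), 0.00096 (0.05/52 class I alleles), 0.0001 (0.05/480
residue columns) — Bonferroni corrections for the respective candidate
counts. A rank guard prevents any candidate lying in the span of the
selected terms (e.g. a duplicated column) from re-entering. Entry
p-values are the conditional Wald p at entry; the reported multivariate
effects come from a joint refit of the final model. Covariates are held
fixed throughout a run.

Under the null with k independent candidates the probability that any
term enters is 1−(1−t)^k (≈5.1% at t=0.0006, k=88); the calibration test
checks the observed rate against the binomial 95% band at the study's own
candidate count.

## Haplotype EM

Haplotype frequencies are estimated by the classic genotype EM under
Hardy–Weinberg equilibrium: the E-step distributes each phase-ambiguous
genotype over its compatible haplotype pairs proportional to the current
frequency products (2·f_i·f_j for heterozygous pairs, f_i² for
homozygous), the M-step re-estimates frequencies from expected counts.
The observed-data log-likelihood is non-decreasing each iteration and is
asserted so on every test run. Convergence: max absolute frequency change
< 1e-8, cap 10,000 iterations; 5 restarts (one uniform, four
Dirichlet-perturbed, seed default 17) with the best final log-likelihood
kept; haplotypes below 1e-6 are pruned from output. Subjects missing any
call at the requested loci are excluded (counted). EM runs separately in
cases and controls — estimating jointly would bias frequencies under
association.

Case/control differences for a haplotype use a 2×2 table of estimated
chromosome counts (frequency × 2N, rounded half-up): chi-square without
continuity correction by default, the exact test when any expected cell is
below 5 — our concrete choice of rule where the source describes "chi
square or Fisher's exact". Using estimated counts ignores phase
uncertainty; this matches the source workflow and is noted, not
corrected. Rounding half-up versus fractional counts changes counts by at
most one chromosome per cell, which is negligible at the cohort sizes
involved.

Pairwise LD between biallelic loci: D = p_AB − p_A·p_B, D′ = D/D_max with
the sign-dependent bound, r² = D²/(p_A p_a p_B p_b); |D′| = 1 whenever a
haplotype class is empty.

## rs67384697 imputation

The HLA-C 3′UTR G/del polymorphism controls hsa-miR-148 binding and HLA-C
surface expression. Because specific four-digit HLA-C alleles are in
near-perfect LD with one state or the other, the del dosage is imputed as
the count of a subject's HLA-C alleles mapping to `del` in a two-column
lookup. The packaged default map is synthetic apart from C*06:02→del
(grounded in its reported complete LD with the deletion); a curated table
should replace it for real analyses, and alleles absent from the map make
the subject's genotype missing rather than guessing. The association of
the imputed dosage delegates to the logistic machinery and supports
conditioning on classical alleles, reproducing the design in which
conditioning on the driving allele attenuates a purely tagging deletion
toward OR 1 while an independent deletion-borne effect survives.

## KIR compound genotype

KIR3DS1 segregates independently of the MHC, so joint carrier status with
Bw4-80I-bearing HLA-B alleles is tested as a single dominant exposure.
Each subject with complete data maps to exactly one of both / KIR-only /
Bw4-only / neither; missing KIR or a fully untyped HLA-B locus is
`incomplete` and excluded per analysis, which is why denominators differ
across the five standard exposures. The odds ratio is the cross-product
(a·d)/(b·c) with a Woolf log-scale 95% CI; a zero cell triggers the
Haldane–Anscombe 0.5 correction with a warning. CI conventions for exact
tests vary between tools, and the CI printed in the source for the
compound row is not the Woolf interval; we report Woolf throughout and
flag the convention here.

The two-sided exact test uses the probability-mass rule: sum the
hypergeometric probabilities of all tables with the observed margins whose
probability is at most the observed table's, with 1e-12 relative slack for
ties. Two-sided Fisher definitions differ across tools; this is the
convention used by the common scientific stacks. The implementation works
in exact integer arithmetic (binomial-coefficient weights), so tie
handling has no floating-point ambiguity; it is verified against an
independent exact-rational enumeration over every table with n ≤ 60 and
against scipy on fixed tables.

A note on printed precision: the source's compound-row OR of 3.92 is the
conditional maximum-likelihood estimate that R's `fisher.test` reports;
the cross-product estimator defined here gives 3.9292 for the same table.
Reproduction tests therefore compare ORs within 0.01.

## Synthetic cohorts

The generator draws two haplotypes per subject from a configurable pool
under HWE (the default pool places a B*57:01–C*06:02-like risk haplotype
at its observed European control frequency, 3.4%, among common
backgrounds), covariates from a sex/cohort/PC model, and KIR3DS1 as an
independent unlinked carrier flag (default carrier frequency 35%).
Disease status follows a logistic model on additive allele/haplotype
dosages, covariates, and an optional KIR×Bw4-80I interaction; case/control
quotas are met by rejection sampling from a base population with default
prevalence 2% — odds ratios, not risks, are the estimands, so the
prevalence only sets the sampling cost. Phase, per-subject risk and the
complete pre-missingness data are kept in a truth record; missingness
(missing-completely-at-random per locus) is applied last. All randomness
flows from one generator, default seed 42.

What the generator does not emulate: realistic MHC recombination and LD
decay beyond the specified pool, genotyping/imputation error, population
demography, or informative missingness. Tests passing on these cohorts
establish the correctness and calibration of the machinery under the
model's own assumptions, not robustness to those real-data features.

A deterministic fixture reproduces the published KIR3DS1/Bw4-80I carrier
analysis exactly. The printed per-row denominators (397/282 KIR-typed,
339/247 B-typed, 331/245 both-typed) are mutually consistent only if the
underlying cohort had 405 cases and 284 controls with partial typing, so
the fixture is built at those totals; every printed numerator, denominator
and percentage then reproduces exactly. The construction is
assertion-checked against all published cells at build time.

## Problem sizes used in the shipped checks

The packaged test suite and the acceptance script run the exhaustive
Fisher sweep at n ≤ 60 (≈6.3×10⁵ tables), EM phase-resolution at n = 2000
subjects per cohort over five-haplotype pools, stepwise calibration at 88
candidates with n = 2000 (null) and n = 4000 (power), and the omnibus
calibration at n = 600 over 1000 (tests) or 500 (script) null replicates —
sizes chosen to make binomial acceptance bands meaningful while keeping a
full run inside a few minutes on one core.

## Known limitations

- The alignment and deletion-map fixtures are partly synthetic stand-ins;
  conclusions about specific residues outside positions 80/116 are not
  biologically meaningful until a curated table is supplied.
- Wald p-values are anti-conservative for very rare dosages; the stepwise
  thresholds assume candidate counts matching the filter output.
- Haplotype case/control tests ignore EM phase uncertainty (by design, to
  mirror the source workflow).
- Heterogeneity (Cochran's Q, I²) uses fixed-effect pooling only; no
  random-effects model is provided.
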