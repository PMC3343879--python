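# hlafinemap

Fine-mapping of classical HLA associations in case/control cohorts: from
allele calls and covariates to allele-, amino-acid-, haplotype- and
compound-genotype-level association results.

The package is aimed at statistical geneticists working on MHC-driven
immune phenotypes (psoriasis-style autoimmune disease, HIV-1 control and
similar), where the question is rarely *whether* the MHC is associated
but *which* alleles, residues and receptor–ligand combinations carry
independent signal through the region's extreme linkage disequilibrium.

## What it computes

- **Additive logistic association** of allele or residue dosages
  g ∈ {0,1,2} with case status, adjusting for sex, cohort and ancestry
  PCs: logit P(y=1) = α + βg + γᵀc, with Wald tests, conditioning by
  covariate inclusion, and candidate filtering at control-group frequency
  > 1%.
- **Amino-acid fine-mapping**: four-digit alleles expanded into
  per-position residue dosages from a positional alignment; single-residue
  tests plus a k−1-df likelihood-ratio **omnibus test** per position; the
  Bw4-80I / Bw4-80T / Bw6 epitope rule at HLA-B position 80; named allele
  groups (B*35 Px/PY).
- **Forward stepwise selection** of independently associated terms with
  Bonferroni stopping thresholds (0.05/k for k candidates: 0.0006,
  0.00096, 0.0001 ship as constants), plus residual-signal conditioning.
- **Haplotype frequencies** by genotype EM under Hardy–Weinberg
  equilibrium, with direct phased counting as cross-check, case/control
  haplotype 2×2 tests and pairwise LD (D′, r²).
- **rs67384697 (HLA-C 3′UTR G/del) imputation** from four-digit HLA-C
  alleles via a configurable LD lookup, with conditional association.
- **KIR3DS1 × Bw4-80I compound genotype**: dominant-model carrier tables,
  exact two-sided Fisher tests in integer arithmetic, cross-product odds
  ratios with Woolf CIs.
- **Cross-cohort heterogeneity**: fixed-effect pooling with Cochran's Q
  and I² = max(0, (Q−df)/Q)·100.
- **Synthetic cohorts** with known truth (haplotype pool, planted
  log-ORs, covariate confounding, unlinked KIR locus with interaction,
  missingness) for validating every stage.

## Worked example

```python
import pandas as pd
from hlafinemap import (
    allele_frequencies, maf_filter, scan, carrier_table, odds_ratio,
    fisher_exact, predicate_compound, default_alignment,
    em_haplotypes, haplotype_case_control_test,
)
from hlafinemap.simulate import SimulationSpec, generate_cohort

spec = SimulationSpec(n_cases=500, n_controls=500, seed=42,
                      allele_effects={"C*06:02": 1.0},
                      kir_interaction_logor=1.2)
cohort, truth = generate_cohort(spec)

kept = maf_filter(allele_frequencies(cohort, "controls"), 0.01)
cand = pd.DataFrame({a: cohort.allele_dosage(a) for a in sorted(kept)})
for r in scan(cohort.phenotype, cand, covariates=cohort.covariate_frame())[:3]:
    print(f"{r.term}  OR={r.or_:.2f}  95% CI=({r.ci95[0]:.2f}, {r.ci95[1]:.2f})  p={r.p:.3g}")

t = carrier_table(cohort, predicate_compound(default_alignment(), "both"))
print(f"compound KIR3DS1+Bw4-80I: {t.a}/{t.n_cases} vs {t.c}/{t.n_controls}, "
      f"OR={odds_ratio(t)[0]:.2f}, Fisher p={fisher_exact(t):.3g}")

est_ca = em_haplotypes(cohort.group("cases"), ["B", "C"], seed=17)
est_co = em_haplotypes(cohort.group("controls"), ["B", "C"], seed=17)
hc = haplotype_case_control_test(est_ca, est_co, ("B*57:01", "C*06:02"))
print(f"B*57:01-C*06:02: {hc['freq_cases']:.3f} vs {hc['freq_controls']:.3f}, "
      f"OR={hc['OR']:.2f}, p={hc['p']:.3g}")
```

prints

```
C*06:02  OR=4.27  95% CI=(3.06, 5.95)  p=9.82e-18
B*57:01  OR=4.67  95% CI=(2.99, 7.31)  p=1.35e-11
B*13:02  OR=3.12  95% CI=(1.98, 4.90)  p=8.78e-07
compound KIR3DS1+Bw4-80I: 145/500 vs 41/500, OR=4.57, Fisher p=1.06e-17
B*57:01-C*06:02: 0.108 vs 0.026, OR=4.54, p=2.24e-13
```

The planted C*06:02 effect surfaces first; B*57:01 and B*13:02 rank high
because they ride C*06:02-bearing haplotypes (LD, not independent
effects — the stepwise stage separates the two); the KIR×Bw4-80I
interaction shows up in the carrier table; and the EM-estimated risk
haplotype is elevated in cases while the control frequency sits near its
base-population value.

A command-line interface wraps the same stages
(`hlafinemap simulate|validate|freqs|scan|stepwise|haplotypes|compound|deletion|compare|run-all`),
driven by a YAML config; results are plain TSV tables plus a JSON run
manifest. See `docs/methods.md` for models, defaults and numerical
choices.

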