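"""Synthetic case/control cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes:
multi-locus haplotypes drawn under Hardy-Weinberg equilibrium from a pool
with strong LD (e.g. a B*57:01–C*06:02-like haplotype), per-allele
log-odds effects on a logistic disease model, covariate confounding by
sex/cohort/ancestry PCs, an unlinked biallelic KIR3DS1 locus, and an
optional KIR × Bw4-80I interaction.  Case/control ascertainment is by
rejection sampling from a base population with configurable prevalence —
odds ratios, not absolute risks, are the estimands.  Phase, covariate
effects and deletion states are retained in a truth record so every
downstream stage can be verified against the generating model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import AlleleCall, CohortTable, SubjectRecord

DEFAULT_SEED = 42

#: Haplotype pool loosely shaped like European B–C LD: a risk haplotype at
#: its observed control frequency (~3.4%), a C*06:02 haplotype without
#: B*57:01, and common neutral backgrounds.
DEFAULT_POOL: list[tuple[tuple[str, ...], float]] = [
    (("B*57:01", "C*06:02"), 0.034),
    (("B*13:02", "C*06:02"), 0.024),
    (("B*07:02", "C*07:02"), 0.112),
    (("B*08:01", "C*07:01"), 0.100),
    (("B*44:02", "C*05:01"), 0.090),
    (("B*40:01", "C*03:04"), 0.048),
    (("B*35:01", "C*04:01"), 0.060),
    (("B*27:05", "C*01:02"), 0.012),
    (("B*18:01", "C*12:03"), 0.040),
    (("B*51:01", "C*15:02"), 0.080),
    (("B*14:02", "C*02:02"), 0.030),
    (("B*55:01", "C*16:01"), 0.370),
]


@dataclass
class SimulationSpec:
    """Generating model for a synthetic cohort.

    Effects are log-odds per dosage unit; ``kir_interaction_logor`` adds to
    the linear predictor when the subject carries KIR3DS1 *and* at least
    one allele from ``bw4_80i_alleles`` (dominant × dominant epistasis).
    ``prevalence`` is the baseline disease risk at zero dosage and average
    covariates.  All randomness flows from a single generator seeded by
    ``seed``.
    """

    loci: tuple[str, ...] = ("B", "C")
    haplotype_pool: list[tuple[tuple[str, ...], float]] = field(
        default_factory=lambda: [(h, f) for h, f in DEFAULT_POOL]
    )
    allele_effects: dict[str, float] = field(default_factory=dict)
    haplotype_effects: dict[tuple[str, ...], float] = field(default_factory=dict)
    kir_interaction_logor: float = 0.0
    kir_main_logor: float = 0.0
    bw4_80i_alleles: frozenset[str] = frozenset({"B*57:01", "B*13:02", "B*38:01", "B*51:01"})
    sex_logor: float = 0.1
    cohort_labels: tuple[str, ...] = ("c1", "c2")
    cohort_logors: tuple[float, ...] = (0.0, 0.15)
    n_pcs: int = 2
    pc_logors: tuple[float, ...] = (0.2, 0.0)
    n_cases: int = 500
    n_controls: int = 500
    prevalence: float = 0.02
    kir_carrier_freq: float = 0.35
    missing_rate: dict[str, float] = field(default_factory=dict)
    kir_missing_rate: float = 0.0
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        tot = sum(f for _, f in self.haplotype_pool)
        if abs(tot - 1.0) > 1e-8:
            raise ValueError(f"haplotype frequencies sum to {tot}, not 1")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("group sizes must be positive")
        for h, _ in self.haplotype_pool:
            if len(h) != len(self.loci):
                raise ValueError(f"haplotype {h} does not match loci {self.loci}")
        for eff in (
            list(self.allele_effects.values())
            + list(self.haplotype_effects.values())
            + [self.kir_interaction_logor, self.kir_main_logor, self.sex_logor]
        ):
            if not np.isfinite(eff):
                raise ValueError("all effect sizes must be finite")


def generate_cohort(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> tuple[CohortTable, dict]:
    """Draw a case/control cohort from the generating model.

    Subjects are sampled from the base population (two pool haplotypes per
    subject, independent KIR, covariates), assigned case status from the
    logistic risk, and kept until both group quotas are met; missingness is
    applied last, after the truth record captures the complete data.
    Raises after a bounded number of attempts if a quota is unreachable.
    """
    spec.validate()
    rng = rng or np.random.default_rng(spec.seed)
    haps = [h for h, _ in spec.haplotype_pool]
    hfreq = np.array([f for _, f in spec.haplotype_pool])
    alpha = float(np.log(spec.prevalence / (1 - spec.prevalence)))
    n_pool = len(haps)

    # per-pool-haplotype effect precomputation makes the risk model vectorisable
    hap_eff = np.zeros(n_pool)
    hap_bw4 = np.zeros(n_pool, dtype=bool)
    for i, h in enumerate(haps):
        hap_eff[i] += sum(eff for a, eff in spec.allele_effects.items() if a in h)
        hap_eff[i] += spec.haplotype_effects.get(h, 0.0)
        hap_bw4[i] = any(a in spec.bw4_80i_alleles for a in h)
    cohort_eff = np.asarray(spec.cohort_logors)
    pc_eff = np.asarray(spec.pc_logors[: spec.n_pcs])

    cases: list[SubjectRecord] = []
    controls: list[SubjectRecord] = []
    truth_rows: list[dict] = []
    max_draws = 2000 * (spec.n_cases + spec.n_controls)
    n_draws = 0
    counter = 0
    allele_cache: dict[tuple[str, str], AlleleCall] = {}
    while (len(cases) < spec.n_cases or len(controls) < spec.n_controls) and n_draws < max_draws:
        batch = min(20_000, max_draws - n_draws)
        n_draws += batch
        i1 = rng.choice(n_pool, size=batch, p=hfreq)
        i2 = rng.choice(n_pool, size=batch, p=hfreq)
        kir = rng.random(batch) < spec.kir_carrier_freq
        female = rng.random(batch) < 0.5
        ci = rng.integers(len(spec.cohort_labels), size=batch)
        pcs = rng.normal(size=(batch, spec.n_pcs))

        eta = alpha + hap_eff[i1] + hap_eff[i2]
        eta += spec.sex_logor * female
        eta += cohort_eff[ci]
        eta += pcs @ pc_eff
        eta += spec.kir_main_logor * kir
        bw4 = hap_bw4[i1] | hap_bw4[i2]
        eta += spec.kir_interaction_logor * (kir & bw4)
        is_case = rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))

        for j in range(batch):
            bucket, quota = (cases, spec.n_cases) if is_case[j] else (controls, spec.n_controls)
            if len(bucket) >= quota:
                continue
            h1, h2 = haps[i1[j]], haps[i2[j]]
            counter += 1
            geno = {}
            for k, L in enumerate(spec.loci):
                pair = []
                for tok in (h1[k], h2[k]):
                    key = (L, tok)
                    if key not in allele_cache:
                        allele_cache[key] = AlleleCall.parse(L, tok)
                    pair.append(allele_cache[key])
                geno[L] = tuple(pair)
            rec = SubjectRecord(
                id=f"S{counter:06d}",
                phenotype="case" if is_case[j] else "control",
                sex="F" if female[j] else "M",
                cohort=spec.cohort_labels[ci[j]],
                pcs=pcs[j],
                genotype=geno,
                kir3ds1=bool(kir[j]),
                phased=(tuple(h1), tuple(h2)),
            )
            bucket.append(rec)
            truth_rows.append(
                {
                    "id": rec.id,
                    "hap1": h1,
                    "hap2": h2,
                    "kir": bool(kir[j]),
                    "eta": float(eta[j]),
                    "bw4": bool(bw4[j]),
                }
            )
            if len(cases) >= spec.n_cases and len(controls) >= spec.n_controls:
                break
    if len(cases) < spec.n_cases or len(controls) < spec.n_controls:
        raise RuntimeError(
            f"could not reach group quotas after {max_draws} draws "
            f"({len(cases)}/{spec.n_cases} cases, {len(controls)}/{spec.n_controls} controls)"
        )

    subjects = cases + controls
    # missingness last: truth keeps the complete data
    for s in subjects:
        for L, rate in spec.missing_rate.items():
            if rate and rng.random() < rate:
                s.genotype[L] = (AlleleCall(L, missing=True), AlleleCall(L, missing=True))
        if spec.kir_missing_rate and rng.random() < spec.kir_missing_rate:
            s.kir3ds1 = None

    table = CohortTable(
        subjects,
        meta={
            "loci": list(spec.loci),
            "phase_loci": list(spec.loci),
            "generator": "hlafinemap.simulate",
            "seed": spec.seed,
        },
    )
    truth = {
        "spec": spec,
        "subjects": truth_rows,
        "pool": spec.haplotype_pool,
        "n_base_draws": n_draws,
    }
    return table, truth


def _block(n: int, prefix: str, phenotype: str, kir, b_pair, start: int) -> list[SubjectRecord]:
    out = []
    for i in range(n):
        geno = {"B": tuple(AlleleCall.parse("B", t) for t in b_pair)} if b_pair else {
            "B": (AlleleCall("B", missing=True), AlleleCall("B", missing=True))
        }
        out.append(
            SubjectRecord(
                id=f"{prefix}{start + i:04d}",
                phenotype=phenotype,
                sex="F" if (start + i) % 2 else "M",
                cohort="kir",
                pcs=np.zeros(1),
                genotype=geno,
                kir3ds1=kir,
            )
        )
    return out


def table6_fixture() -> CohortTable:
    """Deterministic cohort reproducing the published KIR3DS1 × Bw4-80I
    carrier counts, including each analysis's distinct denominator.

    405 cases / 284 controls with planted missingness: 397/282 are
    KIR-typed, 339/247 HLA-B-typed, 331/245 both.  Carrier counts per
    block are chosen so every 2×2 in the published five-row analysis is
    reproduced exactly; the construction is assertion-checked on build.
    """
    BW4 = ("B*57:01", "B*07:02")  # one Bw4-80I allele, one Bw6
    BW6 = ("B*07:02", "B*08:01")
    rows: list[SubjectRecord] = []
    s = 0

    def add(n, pheno, kir, bpair):
        nonlocal s
        rows.extend(_block(n, "K" if pheno == "case" else "L", pheno, kir, bpair, s))
        s += n

    # cases: both-typed 331 = 75 both + 79 kir_only + 76 bw4_only + 101 neither
    add(75, "case", True, BW4)
    add(79, "case", True, BW6)
    add(76, "case", False, BW4)
    add(101, "case", False, BW6)
    # 66 KIR-typed, B-untyped (31 KIR+); 8 B-typed, KIR-untyped (3 Bw4+)
    add(31, "case", True, None)
    add(35, "case", False, None)
    add(3, "case", None, BW4)
    add(5, "case", None, BW6)
    # controls: both-typed 245 = 17 + 63 + 40 + 125
    add(17, "control", True, BW4)
    add(63, "control", True, BW6)
    add(40, "control", False, BW4)
    add(125, "control", False, BW6)
    # 37 KIR-typed, B-untyped (12 KIR+); 2 B-typed, KIR-untyped (1 Bw4+)
    add(12, "control", True, None)
    add(25, "control", False, None)
    add(1, "control", None, BW4)
    add(1, "control", None, BW6)

    table = CohortTable(rows, meta={"loci": ["B"], "fixture": "kir_bw4_carriers"})

    # build-time verification against every published cell
    from .compound import carrier_table, predicate_bw4_80i, predicate_compound, predicate_kir
    from .residues import default_alignment

    aln = default_alignment()
    expect = {
        "both": (75, 256, 17, 228),
        "kir_only": (79, 252, 63, 182),
        "bw4_only": (76, 255, 40, 205),
    }
    for status, cells in expect.items():
        t = carrier_table(table, predicate_compound(aln, status))
        assert (t.a, t.b, t.c, t.d) == cells, (status, t)
    t = carrier_table(table, predicate_kir)
    assert (t.a, t.b, t.c, t.d) == (185, 212, 92, 190), t
    t = carrier_table(table, predicate_bw4_80i(aln))
    assert (t.a, t.b, t.c, t.d) == (154, 185, 58, 189), t
    return table
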