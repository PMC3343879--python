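"""EM haplotype estimation, phased counting, case/control tests, LD."""

import numpy as np
import pytest

from hlafinemap import (
    CohortTable,
    allele_frequencies,
    count_phased,
    em_haplotypes,
    haplotype_case_control_test,
    ld_pair,
)
from hlafinemap.simulate import SimulationSpec, generate_cohort

from conftest import make_cohort, make_subject


def two_locus_cohort(n_aabb, n_xxyy, n_het):
    """AABB / aabb / AaBb cohort on HLA-B/C alleles (A=B*57:01, B=C*06:02)."""
    subs = []
    i = 0
    for _ in range(n_aabb):
        i += 1
        subs.append(make_subject(f"s{i}", B=("B*57:01", "B*57:01"), C=("C*06:02", "C*06:02")))
    for _ in range(n_xxyy):
        i += 1
        subs.append(make_subject(f"s{i}", B=("B*07:02", "B*07:02"), C=("C*07:02", "C*07:02")))
    for _ in range(n_het):
        i += 1
        subs.append(make_subject(f"s{i}", B=("B*57:01", "B*07:02"), C=("C*06:02", "C*07:02")))
    return make_cohort(subs, loci=["B", "C"])


def grid_search_mle(n_aabb, n_xxyy, n_het, grid=2_000_001):
    """Brute-force 1-D likelihood maximisation for the double-heterozygote
    instance: with allele margins fixed by the data, f(AB)=t is the single
    free parameter; f(Ab)=f(aB)=pA-t, f(ab)=1-2*pA+t."""
    n = n_aabb + n_xxyy + n_het
    pA = (2 * n_aabb + n_het) / (2 * n)
    lo, hi = max(0.0, 2 * pA - 1.0), pA
    t = np.linspace(lo, hi, grid)[1:-1]
    fAB, fAb, fab = t, pA - t, 1 - 2 * pA + t
    ll = (
        2 * n_aabb * np.log(fAB)
        + 2 * n_xxyy * np.log(fab)
        + n_het * np.log(2 * fAB * fab + 2 * fAb**2)
    )
    return float(t[np.argmax(ll)])


class TestEM:
    def test_single_locus_equals_allele_frequencies(self, bc_cohort):
        est = em_haplotypes(bc_cohort, ["B"])
        freqs = allele_frequencies(bc_cohort, "all", loci=["B"])
        # s5's half-missing genotype is excluded by the EM (complete-case)
        sub = CohortTable([s for s in bc_cohort if not any(c.missing for c in s.calls("B"))],
                          dict(bc_cohort.meta))
        freqs = allele_frequencies(sub, "all", loci=["B"])
        for (name,), f in est.freqs.items():
            assert f == pytest.approx(freqs[name], abs=1e-9)

    def test_all_homozygous_equals_direct_counting(self):
        cohort = two_locus_cohort(50, 50, 0)
        est = em_haplotypes(cohort, ["B", "C"])
        assert est.frequency(("B*57:01", "C*06:02")) == pytest.approx(0.5, abs=1e-12)
        assert est.frequency(("B*07:02", "C*07:02")) == pytest.approx(0.5, abs=1e-12)

    def test_50_50_10_matches_grid_search(self):
        cohort = two_locus_cohort(50, 50, 10)
        est = em_haplotypes(cohort, ["B", "C"])
        t_star = grid_search_mle(50, 50, 10)
        assert est.frequency(("B*57:01", "C*06:02")) == pytest.approx(t_star, abs=1e-6)

    def test_loglik_monotone_nondecreasing(self):
        spec = SimulationSpec(n_cases=100, n_controls=100, seed=21)
        cohort, _ = generate_cohort(spec)
        est = em_haplotypes(cohort, ["B", "C"])
        tr = est.loglik_trace
        assert all(tr[i + 1] >= tr[i] - 1e-9 for i in range(len(tr) - 1))

    def test_subject_order_invariance_and_determinism(self, rng):
        spec = SimulationSpec(n_cases=80, n_controls=80, seed=31)
        cohort, _ = generate_cohort(spec)
        est1 = em_haplotypes(cohort, ["B", "C"], seed=17)
        order = rng.permutation(len(cohort))
        shuffled = CohortTable([cohort.subjects[i] for i in order], dict(cohort.meta))
        est2 = em_haplotypes(shuffled, ["B", "C"], seed=17)
        assert set(est1.freqs) == set(est2.freqs)
        for h in est1.freqs:
            assert est1.freqs[h] == pytest.approx(est2.freqs[h], abs=1e-9)

    def test_em_matches_phased_truth(self):
        spec = SimulationSpec(n_cases=200, n_controls=800, seed=41)
        cohort, _ = generate_cohort(spec)
        est = em_haplotypes(cohort.group("controls"), ["B", "C"])
        counted = count_phased(cohort.group("controls"), ["B", "C"])
        for hap, f in counted.items():
            if f > 0.01:
                assert est.frequency(hap) == pytest.approx(f, abs=0.01)

    def test_no_complete_subjects_errors(self):
        subs = [make_subject("a", B=("B*57:01", None), C=("C*06:02", "C*06:02"))]
        with pytest.raises(ValueError, match="complete"):
            em_haplotypes(make_cohort(subs, loci=["B", "C"]), ["B", "C"])

    def test_empty_locus_list_errors(self, bc_cohort):
        with pytest.raises(ValueError):
            em_haplotypes(bc_cohort, [])


class TestCountPhased:
    def test_single_haplotype_population(self):
        subs = [
            make_subject(
                f"s{i}",
                B=("B*57:01", "B*57:01"),
                C=("C*06:02", "C*06:02"),
                phased=(("B*57:01", "C*06:02"), ("B*57:01", "C*06:02")),
            )
            for i in range(5)
        ]
        cohort = make_cohort(subs, loci=["B", "C"])
        cohort.meta["phase_loci"] = ["B", "C"]
        assert count_phased(cohort, ["B", "C"]) == {("B*57:01", "C*06:02"): 1.0}

    def test_missing_phase_errors(self, bc_cohort):
        with pytest.raises(ValueError, match="phase"):
            count_phased(bc_cohort, ["B", "C"])


class TestCaseControlTest:
    @staticmethod
    def _est(freqs, n_chrom, loci=("B", "C")):
        from hlafinemap.haplotypes import HaplotypeFrequencyEstimate

        return HaplotypeFrequencyEstimate(
            loci=tuple(loci), freqs=freqs, loglik=0.0, n_iter=1, converged=True,
            n_chromosomes=n_chrom,
        )

    def test_equal_frequencies_null(self):
        hap = ("B*57:01", "C*06:02")
        est_ca = self._est({hap: 0.2, ("B*07:02", "C*07:02"): 0.8}, 1000)
        est_co = self._est({hap: 0.2, ("B*07:02", "C*07:02"): 0.8}, 1000)
        r = haplotype_case_control_test(est_ca, est_co, hap)
        assert r["OR"] == pytest.approx(1.0, abs=1e-12)
        assert r["p"] > 0.9

    def test_or_close_to_odds_form(self):
        hap = ("B*57:01", "C*06:02")
        est_ca = self._est({hap: 0.12, ("x", "y"): 0.88}, 3000)
        est_co = self._est({hap: 0.03, ("x", "y"): 0.97}, 6000)
        r = haplotype_case_control_test(est_ca, est_co, hap)
        expected = (0.12 / 0.88) / (0.03 / 0.97)
        assert abs(r["OR"] - expected) / expected < 0.2

    def test_zero_cell_takes_exact_path(self):
        hap = ("B*57:01", "C*06:02")
        est_ca = self._est({hap: 0.02, ("x", "y"): 0.98}, 200)
        est_co = self._est({("x", "y"): 1.0}, 200)
        r = haplotype_case_control_test(est_ca, est_co, hap)
        assert r["method"] == "fisher"
        assert 0 < r["p"] <= 1

    def test_absent_haplotype_errors(self):
        est = self._est({("x", "y"): 1.0}, 100)
        with pytest.raises(ValueError, match="absent"):
            haplotype_case_control_test(est, est, ("B*57:01", "C*06:02"))

    def test_mismatched_loci_error(self):
        est1 = self._est({("x", "y"): 1.0}, 100, loci=("B", "C"))
        est2 = self._est({("x",): 1.0}, 100, loci=("B",))
        with pytest.raises(ValueError, match="loci"):
            haplotype_case_control_test(est1, est2, ("x", "y"))


class TestLD:
    def test_independent_loci(self):
        freqs = {("A", "B"): 0.06, ("A", "b"): 0.14, ("a", "B"): 0.24, ("a", "b"): 0.56}
        ld = ld_pair(freqs)
        assert ld.d_prime == pytest.approx(0.0, abs=1e-12)
        assert ld.r2 == pytest.approx(0.0, abs=1e-12)

    def test_complete_association_equal_freqs(self):
        freqs = {("A", "B"): 0.3, ("a", "b"): 0.7}
        ld = ld_pair({**freqs, ("A", "b"): 0.0, ("a", "B"): 0.0})
        assert ld.d_prime == pytest.approx(1.0)
        assert ld.r2 == pytest.approx(1.0)

    def test_missing_class_unequal_freqs(self):
        # one haplotype class empty but pA != pB: |D'|=1, r2 < 1
        freqs = {("A", "B"): 0.2, ("A", "b"): 0.0, ("a", "B"): 0.3, ("a", "b"): 0.5}
        ld = ld_pair(freqs)
        assert ld.d_prime == pytest.approx(1.0)
        assert ld.r2 < 1.0

    def test_monomorphic_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            ld_pair({("A", "B"): 0.5, ("A", "b"): 0.5, ("a", "B"): 0.0, ("a", "b"): 0.0})
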