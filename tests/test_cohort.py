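"""Data model, file round-trips, allele nomenclature and frequency filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from hlafinemap import (
    AlleleCall,
    CohortTable,
    CohortValidationError,
    allele_frequencies,
    carrier_frequency,
    maf_filter,
    read_cohort,
    write_cohort,
)
from hlafinemap.simulate import SimulationSpec, generate_cohort

from conftest import make_cohort, make_subject


class TestAlleleCall:
    @pytest.mark.parametrize(
        "token, name, resolution",
        [
            ("B*57:01", "B*57:01", "four_digit"),
            ("57:01", "B*57:01", "four_digit"),
            ("B*57", "B*57", "two_digit"),
            ("C*06", "C*06", "two_digit"),
            ("7:02", "B*07:02", "four_digit"),  # zero-padding normalised
        ],
    )
    def test_parse_who_nomenclature(self, token, name, resolution):
        call = AlleleCall.parse("B" if name.startswith("B") else "C", token)
        assert call.name == name
        assert call.resolution == resolution
        assert not call.missing

    @pytest.mark.parametrize("token", ["B*5701", "B57:01", "X*57:01", "B*xx:01"])
    def test_malformed_tokens_name_the_token(self, token):
        with pytest.raises(CohortValidationError, match="B"):
            AlleleCall.parse("B", token)

    def test_missing_tokens(self):
        for tok in ("", "NA", "-", "."):
            assert AlleleCall.parse("B", tok).missing

    def test_locus_mismatch_rejected(self):
        with pytest.raises(CohortValidationError):
            AlleleCall.parse("C", "B*57:01")

    def test_collapse_truncates_at_colon(self):
        assert AlleleCall.parse("B", "B*57:01").collapse().name == "B*57"


class TestCohortIO:
    def test_round_trip_is_identity(self, tmp_path, bc_cohort):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_cohort(bc_cohort, p1)
        back = read_cohort(p1)
        write_cohort(back, p2)
        assert p1.read_text() == p2.read_text()
        assert back.ids == bc_cohort.ids
        assert [s.kir3ds1 for s in back] == [s.kir3ds1 for s in bc_cohort]
        for s0, s1 in zip(bc_cohort, back):
            assert s0.genotype == s1.genotype

    def test_malformed_row_reports_line_and_token(self, tmp_path, bc_cohort):
        path = tmp_path / "bad.tsv"
        write_cohort(bc_cohort, path)
        text = path.read_text().replace("B*57:01\tB*07:02", "B*5701\tB*07:02")
        path.write_text(text)
        with pytest.raises(CohortValidationError, match=r"line 2.*B\*5701"):
            read_cohort(path)

    def test_two_digit_calls_record_resolution(self, tmp_path):
        cohort = make_cohort(
            [
                make_subject("a", "case", C=("C*06", "C*07")),
                make_subject("b", "control", C=("C*06", "C*04")),
            ],
            loci=["C"],
        )
        path = tmp_path / "two.tsv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        calls = back.subjects[0].calls("C")
        assert all(c.resolution == "two_digit" for c in calls)

    def test_duplicate_ids_rejected(self):
        subs = [make_subject("dup", B=("B*57:01", "B*57:01")) for _ in range(2)]
        with pytest.raises(CohortValidationError, match="dup"):
            CohortTable(subs)

    def test_missing_calls_preserved_not_dropped(self, tmp_path, bc_cohort):
        path = tmp_path / "m.tsv"
        write_cohort(bc_cohort, path)
        back = read_cohort(path)
        a, b = back.subjects[4].calls("B")  # s5 has one missing B call
        assert b.missing and not a.missing


class TestFrequencies:
    def test_homozygote_frequency_one(self):
        cohort = make_cohort([make_subject("a", B=("B*57:01", "B*57:01"))], loci=["B"])
        assert allele_frequencies(cohort)["B*57:01"] == 1.0

    def test_sum_to_one_per_locus(self, bc_cohort):
        freqs = allele_frequencies(bc_cohort, "all")
        for locus in ("B", "C"):
            tot = sum(f for a, f in freqs.items() if a.startswith(locus + "*"))
            assert tot == pytest.approx(1.0, abs=1e-12)

    def test_missing_chromosomes_excluded_from_denominator(self, bc_cohort):
        freqs = allele_frequencies(bc_cohort, "controls")
        # controls contribute 5 non-missing B chromosomes (s5 has one missing)
        assert freqs["B*35:01"] == pytest.approx(1 / 5)

    def test_empty_group_errors(self):
        cohort = make_cohort([make_subject("a", B=("B*57:01", "B*57:01"))], loci=["B"])
        with pytest.raises(ValueError):
            allele_frequencies(cohort, "cases")

    def test_carrier_frequency_dominant(self):
        subs = [
            make_subject(f"c{i}", "case", B=("B*57:01", "B*07:02")) for i in range(75)
        ] + [make_subject(f"n{i}", "case", B=("B*07:02", "B*07:02")) for i in range(256)]
        cohort = make_cohort(subs, loci=["B"])
        assert carrier_frequency(cohort, "B*57:01", "cases") == pytest.approx(75 / 331)

    def test_estimate_within_3se_of_generating_frequency(self):
        spec = SimulationSpec(n_cases=100, n_controls=1900, seed=11)
        cohort, _ = generate_cohort(spec)
        freqs = allele_frequencies(cohort, "controls")
        p0 = dict((h[0], f) for (h, f) in spec.haplotype_pool)["B*57:01"]
        se = np.sqrt(p0 * (1 - p0) / (2 * 1900))
        assert abs(freqs["B*57:01"] - p0) < 3 * se


class TestMafFilter:
    def test_strict_inequality_at_boundary(self):
        freqs = {"B*57:01": 0.010, "B*13:02": 0.0101, "B*07:02": 0.0}
        kept = maf_filter(freqs, 0.01)
        assert kept == {"B*13:02"}

    def test_case_frequency_never_consulted(self, rng):
        # filter on controls is invariant to any change among cases
        spec = SimulationSpec(n_cases=150, n_controls=150, seed=5)
        cohort, _ = generate_cohort(spec)
        ctrl = allele_frequencies(cohort, "controls")
        kept = maf_filter(ctrl, 0.01)
        perm = [s for s in cohort]
        rng.shuffle(perm)
        for s in perm[:50]:
            if s.phenotype == "case":
                s.genotype["B"] = s.genotype["B"][::-1]
        ctrl2 = allele_frequencies(CohortTable(perm, cohort.meta), "controls")
        assert maf_filter(ctrl2, 0.01) == kept

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            maf_filter({"B*57:01": 0.2}, 0.7)


@settings(max_examples=25, deadline=None)
@given(hst.integers(min_value=1, max_value=2**31 - 1))
def test_frequency_sum_invariant_random_cohorts(seed):
    """Per-locus frequencies over non-missing chromosomes always sum to 1."""
    spec = SimulationSpec(n_cases=30, n_controls=30, seed=seed, missing_rate={"B": 0.2})
    cohort, _ = generate_cohort(spec)
    freqs = allele_frequencies(cohort, "all")
    for locus in ("B", "C"):
        tot = sum(f for a, f in freqs.items() if a.startswith(locus + "*"))
        assert abs(tot - 1.0) < 1e-12
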