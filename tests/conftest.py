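"""Shared fixtures: tiny hand-built cohorts and the packaged alignment."""

from __future__ import annotations

import numpy as np
import pytest

from hlafinemap import AlleleCall, CohortTable, SubjectRecord, default_alignment


def make_subject(
    uid: str,
    phenotype: str = "control",
    sex: str = "F",
    cohort: str = "c1",
    pcs=None,
    kir3ds1=None,
    phased=None,
    **locus_pairs,
) -> SubjectRecord:
    """Build a subject from keyword locus pairs, e.g. B=("B*57:01", None)."""
    geno = {}
    for locus, pair in locus_pairs.items():
        calls = []
        for tok in pair:
            if tok is None:
                calls.append(AlleleCall(locus, missing=True))
            else:
                calls.append(AlleleCall.parse(locus, tok))
        geno[locus] = tuple(calls)
    return SubjectRecord(
        id=uid,
        phenotype=phenotype,
        sex=sex,
        cohort=cohort,
        pcs=np.asarray(pcs if pcs is not None else [0.0]),
        genotype=geno,
        kir3ds1=kir3ds1,
        phased=phased,
    )


def make_cohort(subjects, loci=None) -> CohortTable:
    meta = {"loci": loci} if loci else {}
    return CohortTable(list(subjects), meta)


@pytest.fixture(scope="session")
def alignment():
    return default_alignment()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def bc_cohort():
    """Six subjects over HLA-B/C with one missing call and a KIR flag."""
    subs = [
        make_subject("s1", "case", B=("B*57:01", "B*07:02"), C=("C*06:02", "C*07:02"), kir3ds1=True),
        make_subject("s2", "case", B=("B*57:01", "B*57:01"), C=("C*06:02", "C*06:02"), kir3ds1=False),
        make_subject("s3", "case", B=("B*27:05", "B*08:01"), C=("C*01:02", "C*07:01"), kir3ds1=True),
        make_subject("s4", "control", B=("B*07:02", "B*07:02"), C=("C*07:02", "C*07:02"), kir3ds1=False),
        make_subject("s5", "control", B=("B*35:01", None), C=("C*04:01", "C*04:01"), kir3ds1=None),
        make_subject("s6", "control", B=("B*40:01", "B*08:01"), C=("C*03:04", "C*07:01"), kir3ds1=True),
    ]
    return make_cohort(subs, loci=["B", "C"])
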