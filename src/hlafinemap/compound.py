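"""Carrier-level 2×2 inference, including the KIR3DS1 × Bw4-80I compound genotype.

KIR3DS1 (an activating NK-cell receptor gene on chromosome 19) and its
putative ligand — HLA-B alleles bearing the Bw4-80I epitope — segregate
independently, so their joint carrier status ("compound genotype") is a
genuine two-locus exposure rather than a linkage artefact.  Analyses here
are dominant-model: a subject is exposed if they carry at least one copy.

The exact test uses the probability-mass definition of the two-sided
p-value: with margins fixed, sum the hypergeometric probabilities of every
table whose probability does not exceed the observed table's (a relative
slack of 1e-12 absorbs ties).  Weights are exact integers (binomial
coefficients), so the computation has no floating-point tie ambiguity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from math import comb, sqrt
from typing import Callable

import numpy as np

from .cohort import CohortTable, SubjectRecord
from .residues import ProteinAlignment, classify_bw

logger = logging.getLogger("hlafinemap")

COMPOUND_STATES = ("both", "kir_only", "bw4_only", "neither", "incomplete")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a=exposed cases, b=unexposed cases, c=exposed controls, d=unexposed controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError(f"counts must be nonnegative integers, got {self!r}")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d


def compound_status(subject: SubjectRecord, alignment: ProteinAlignment) -> str:
    """Joint KIR3DS1 / Bw4-80I carrier category of one subject.

    Bw4-80I positivity = at least one HLA-B allele classified ``Bw4_80I``
    (dominant model).  Missing KIR status or a fully untyped HLA-B locus
    yields ``incomplete`` — a value, not an error — so per-analysis
    denominators can differ with missingness.
    """
    a, b = subject.calls("B")
    if subject.kir3ds1 is None or (a.missing and b.missing):
        return "incomplete"
    bw4 = any(
        not call.missing and classify_bw(call, alignment) == "Bw4_80I" for call in (a, b)
    )
    if subject.kir3ds1 and bw4:
        return "both"
    if subject.kir3ds1:
        return "kir_only"
    if bw4:
        return "bw4_only"
    return "neither"


def odds_ratio(table: ContingencyTable2x2) -> tuple[float, tuple[float, float]]:
    """Cross-product odds ratio with a Woolf (log) 95% CI.

    A zero cell triggers the Haldane-Anscombe 0.5 correction with a
    warning; a zero margin is an error (the OR is undefined).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ValueError(f"zero margin in {table!r}: odds ratio undefined")
    if min(a, b, c, d) == 0:
        warnings.warn("zero cell: applying Haldane-Anscombe 0.5 correction", UserWarning)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    half = 1.959963984540054 * se
    lo, hi = or_ * np.exp(-half), or_ * np.exp(half)
    return float(or_), (float(lo), float(hi))


_TIE_SLACK = 1e-12


def fisher_exact(table: ContingencyTable2x2, sided: str = "two") -> float:
    """Fisher's exact test p-value on a 2×2 table.

    ``sided="two"``: probability-mass rule (sum of P(table') for all tables
    with the observed margins and P(table') <= P(observed)·(1+1e-12)).
    ``sided="greater"``/``"less"`` are one-sided tails in the exposed-case
    cell.  Exact integer arithmetic throughout.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)]
    total = sum(weights)
    if total == 0:
        return 1.0
    w_obs = weights[a - lo]
    if sided == "greater":
        num = sum(weights[k - lo] for k in range(a, hi + 1))
    elif sided == "less":
        num = sum(weights[k - lo] for k in range(lo, a + 1))
    elif sided == "two":
        # integer-safe form of w <= w_obs * (1 + slack)
        num = sum(w for w in weights if w * 10**18 <= w_obs * (10**18 + 10**6))
    else:
        raise ValueError(f"sided must be two/greater/less, got {sided!r}")
    return min(1.0, num / total)


def carrier_table(
    cohort: CohortTable, predicate: Callable[[SubjectRecord], bool | None]
) -> ContingencyTable2x2:
    """Dominant-model 2×2 table from a per-subject predicate.

    ``predicate`` returns True/False for exposed/unexposed and None for
    subjects with incomplete data, who are excluded (count logged) — this
    is what produces differing denominators across analyses when
    missingness differs between exposures.
    """
    a = b = c = d = 0
    n_incomplete = 0
    for s in cohort:
        flag = predicate(s)
        if flag is None:
            n_incomplete += 1
            continue
        if s.phenotype == "case":
            a, b = (a + 1, b) if flag else (a, b + 1)
        else:
            c, d = (c + 1, d) if flag else (c, d + 1)
    if (a + b) == 0 or (c + d) == 0:
        raise ValueError("carrier_table: a group is empty after exclusions")
    if n_incomplete:
        logger.info("carrier_table: %d subjects excluded as incomplete", n_incomplete)
    return ContingencyTable2x2(a, b, c, d)


# Predicates for the five standard exposures -------------------------------


def predicate_kir(subject: SubjectRecord) -> bool | None:
    """KIR3DS1 carrier (None if untyped)."""
    return subject.kir3ds1


def predicate_bw4_80i(alignment: ProteinAlignment) -> Callable[[SubjectRecord], bool | None]:
    """Bw4-80I carrier (requires at least one non-missing HLA-B call)."""

    def pred(s: SubjectRecord) -> bool | None:
        a, b = s.calls("B")
        if a.missing and b.missing:
            return None
        return any(
            not call.missing and classify_bw(call, alignment) == "Bw4_80I" for call in (a, b)
        )

    return pred


def predicate_compound(
    alignment: ProteinAlignment, status: str = "both"
) -> Callable[[SubjectRecord], bool | None]:
    """Exposure = a given :func:`compound_status` category; incomplete → None."""
    if status not in COMPOUND_STATES[:4]:
        raise ValueError(f"status must be one of {COMPOUND_STATES[:4]}")

    def pred(s: SubjectRecord) -> bool | None:
        st = compound_status(s, alignment)
        return None if st == "incomplete" else st == status

    return pred
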