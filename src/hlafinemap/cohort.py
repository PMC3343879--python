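"""Case/control HLA cohort data model and I/O.

A cohort is a table of subjects, one row each, carrying a binary phenotype,
sex, a cohort-of-origin label, ancestry principal-component scores, two
classical HLA allele calls per locus in WHO nomenclature (``B*57:01``), and
an optional KIR3DS1 presence flag.  Allele calls may be at two-field
("four-digit", protein-level) or one-field ("two-digit", allele-group)
resolution; the two resolutions are analysed in separate runs, with
four-digit names collapsed by truncation at the first colon.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hlafinemap")

#: Classical HLA loci handled by the pipeline, in canonical order.
LOCI: tuple[str, ...] = ("A", "B", "C", "DQA1", "DQB1", "DRB1")

#: Tokens accepted as a missing allele call in input files.
MISSING_TOKENS = frozenset({"", "na", "nan", "none", ".", "-", "?"})

_ALLELE_RE = re.compile(r"^(?:(?P<locus>[A-Z]+[0-9]*)\*)?(?P<g1>\d{1,3})(?::(?P<g2>\d{1,3}))?$")


class CohortValidationError(ValueError):
    """Raised when a cohort file or record violates the data contract."""


@dataclass(frozen=True)
class AlleleCall:
    """One classical HLA allele call in WHO nomenclature.

    ``resolution`` is ``"four_digit"`` for two-field names (``B*57:01``,
    protein-level) and ``"two_digit"`` for one-field names (``B*57``).
    A missing call has ``missing=True`` and an empty name.
    """

    locus: str
    name: str = ""
    resolution: str = "four_digit"
    missing: bool = False

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise CohortValidationError(f"unknown HLA locus {self.locus!r}")
        if not self.missing:
            m = _ALLELE_RE.match(self.name)
            if m is None or m.group("locus") != self.locus:
                raise CohortValidationError(
                    f"allele name {self.name!r} does not parse at locus {self.locus}"
                )
            want = "four_digit" if m.group("g2") else "two_digit"
            if want != self.resolution:
                raise CohortValidationError(
                    f"allele {self.name!r} is {want}, not {self.resolution}"
                )

    @classmethod
    def parse(cls, locus: str, token: object) -> "AlleleCall":
        """Parse a file token into an :class:`AlleleCall`.

        Accepts ``B*57:01`` or bare ``57:01`` (the locus is then taken from
        the column).  Missing tokens (``NA``, ``-`` ...) yield a missing call.
        """
        text = "" if token is None else str(token).strip()
        if text.lower() in MISSING_TOKENS:
            return cls(locus=locus, missing=True)
        m = _ALLELE_RE.match(text)
        if m is None:
            raise CohortValidationError(f"unparseable allele token {text!r} at locus {locus}")
        if m.group("locus") is not None and m.group("locus") != locus:
            raise CohortValidationError(
                f"allele token {text!r} names locus {m.group('locus')}, expected {locus}"
            )
        g1, g2 = m.group("g1"), m.group("g2")
        if g2 is None:
            return cls(locus=locus, name=f"{locus}*{int(g1):02d}", resolution="two_digit")
        return cls(locus=locus, name=f"{locus}*{int(g1):02d}:{int(g2):02d}")

    def collapse(self) -> "AlleleCall":
        """Truncate a four-digit call to its two-digit allele group."""
        if self.missing or self.resolution == "two_digit":
            return AlleleCall(self.locus, self.name, "two_digit", self.missing)
        return AlleleCall(self.locus, self.name.split(":")[0], "two_digit")


@dataclass
class SubjectRecord:
    """One subject: phenotype, covariates, diploid HLA calls, optional KIR."""

    id: str
    phenotype: str  # "case" | "control"
    sex: str
    cohort: str
    pcs: np.ndarray
    genotype: dict[str, tuple[AlleleCall, AlleleCall]]
    kir3ds1: bool | None = None
    #: Phased haplotypes (two tuples of allele names ordered like the locus
    #: list used at generation time), present only when phase is known.
    phased: tuple[tuple[str, ...], tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        if self.phenotype not in ("case", "control"):
            raise CohortValidationError(
                f"subject {self.id}: phenotype must be case/control, got {self.phenotype!r}"
            )
        for locus, pair in self.genotype.items():
            if len(pair) != 2:
                raise CohortValidationError(
                    f"subject {self.id}: locus {locus} needs exactly two calls"
                )

    def calls(self, locus: str) -> tuple[AlleleCall, AlleleCall]:
        return self.genotype.get(locus, (AlleleCall(locus, missing=True),) * 2)

    def carries(self, allele: str) -> bool | None:
        """Dominant-model carrier status for a named allele; None if the
        locus is untyped for this subject."""
        locus = allele.split("*")[0]
        a, b = self.calls(locus)
        if a.missing and b.missing:
            return None
        return allele in (a.name, b.name)


@dataclass
class CohortTable:
    """Ordered collection of subjects plus provenance metadata."""

    subjects: list[SubjectRecord]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate subject ids: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.subjects]

    @property
    def phenotype(self) -> np.ndarray:
        """0/1 vector, 1 = case."""
        return np.array([1 if s.phenotype == "case" else 0 for s in self.subjects])

    def group(self, which: str) -> "CohortTable":
        if which == "all":
            return self
        if which not in ("cases", "controls"):
            raise ValueError(f"group must be cases/controls/all, got {which!r}")
        pheno = "case" if which == "cases" else "control"
        subs = [s for s in self.subjects if s.phenotype == pheno]
        return CohortTable(subs, dict(self.meta, subset=which))

    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    def n_controls(self) -> int:
        return len(self) - self.n_cases()

    def collapse_two_digit(self) -> "CohortTable":
        """Return a cohort with all calls truncated to two-digit groups."""
        subs = []
        for s in self.subjects:
            geno = {L: (a.collapse(), b.collapse()) for L, (a, b) in s.genotype.items()}
            subs.append(
                SubjectRecord(s.id, s.phenotype, s.sex, s.cohort, s.pcs, geno, s.kir3ds1, s.phased)
            )
        return CohortTable(subs, dict(self.meta, resolution="two_digit"))

    def covariate_frame(self, n_pcs: int | None = None) -> pd.DataFrame:
        """Design-ready covariates: sex and cohort indicators (first level
        dropped) plus the leading ``n_pcs`` principal-component scores."""
        rows = {}
        sexes = sorted({s.sex for s in self.subjects})
        cohorts = sorted({s.cohort for s in self.subjects})
        for lvl in sexes[1:]:
            rows[f"sex_{lvl}"] = [1.0 if s.sex == lvl else 0.0 for s in self.subjects]
        for lvl in cohorts[1:]:
            rows[f"cohort_{lvl}"] = [1.0 if s.cohort == lvl else 0.0 for s in self.subjects]
        k = min(len(s.pcs) for s in self.subjects) if self.subjects else 0
        if n_pcs is not None:
            k = min(k, n_pcs)
        for j in range(k):
            rows[f"pc{j + 1}"] = [float(s.pcs[j]) for s in self.subjects]
        return pd.DataFrame(rows, index=self.ids)

    def allele_dosage(self, allele: str) -> pd.Series:
        """Additive 0/1/2 dosage of a named allele; NaN where untyped."""
        locus = allele.split("*")[0]
        out = []
        for s in self.subjects:
            a, b = s.calls(locus)
            if a.missing or b.missing:
                out.append(np.nan)
            else:
                out.append(float((a.name == allele) + (b.name == allele)))
        return pd.Series(out, index=self.ids, name=allele)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

DEFAULT_SCHEMA: dict = {
    "id": "id",
    "phenotype": "phenotype",
    "sex": "sex",
    "cohort": "cohort",
    "kir3ds1": "kir3ds1",
    "loci": list(LOCI),
    "delimiter": "\t",
}

_PHENO_MAP = {"case": "case", "1": "case", "2": "case", "control": "control", "0": "control"}


def read_cohort(path: str | Path, schema: Mapping | None = None) -> CohortTable:
    """Read a delimiter-separated cohort file into a :class:`CohortTable`.

    The file has a header; per-locus calls live in ``<locus>_1``/``<locus>_2``
    columns, PCs in ``pc1..pcK``, and phase (optional) in ``hap1``/``hap2``
    columns of ``~``-joined allele names.  Malformed rows are reported with
    their line number and the offending token.
    """
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sch["delimiter"], dtype=str, keep_default_na=False)
    if schema is not None and "loci" in schema:
        loci = list(sch["loci"])
    else:  # auto-detect the loci present in the file
        loci = [L for L in LOCI if f"{L}_1" in df.columns and f"{L}_2" in df.columns]
        if not loci:
            raise CohortValidationError(f"{path.name}: no <locus>_1/<locus>_2 columns found")
    required = [sch["id"], sch["phenotype"], sch["sex"], sch["cohort"]]
    required += [f"{L}_{i}" for L in loci for i in (1, 2)]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise CohortValidationError(f"{path.name}: missing columns {missing_cols}")
    pc_cols = sorted(
        (c for c in df.columns if re.fullmatch(r"pc\d+", c)), key=lambda c: int(c[2:])
    )

    subjects: list[SubjectRecord] = []
    errors: list[str] = []
    for row_ix, row in df.iterrows():
        line = row_ix + 2  # header is line 1
        try:
            pheno_raw = row[sch["phenotype"]].strip().lower()
            if pheno_raw not in _PHENO_MAP:
                raise CohortValidationError(f"phenotype token {pheno_raw!r}")
            geno = {}
            for L in loci:
                geno[L] = (
                    AlleleCall.parse(L, row[f"{L}_1"]),
                    AlleleCall.parse(L, row[f"{L}_2"]),
                )
            kir: bool | None = None
            if sch["kir3ds1"] in df.columns:
                tok = row[sch["kir3ds1"]].strip().lower()
                if tok not in MISSING_TOKENS:
                    kir = tok in ("1", "true", "yes", "present")
            phased = None
            if "hap1" in df.columns and "hap2" in df.columns:
                h1, h2 = row["hap1"].strip(), row["hap2"].strip()
                if h1 and h2:
                    phased = (tuple(h1.split("~")), tuple(h2.split("~")))
            subjects.append(
                SubjectRecord(
                    id=row[sch["id"]].strip(),
                    phenotype=_PHENO_MAP[pheno_raw],
                    sex=row[sch["sex"]].strip(),
                    cohort=row[sch["cohort"]].strip(),
                    pcs=np.array([float(row[c]) for c in pc_cols]),
                    genotype=geno,
                    kir3ds1=kir,
                    phased=phased,
                )
            )
        except (CohortValidationError, ValueError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise CohortValidationError(f"{path.name}: " + "; ".join(errors[:10]))
    table = CohortTable(subjects, meta={"source": str(path), "loci": loci})
    n_pcs = {len(s.pcs) for s in subjects}
    if len(n_pcs) > 1:
        raise CohortValidationError(f"{path.name}: inconsistent PC vector lengths {sorted(n_pcs)}")
    return table


def write_cohort(cohort: CohortTable, path: str | Path, delimiter: str = "\t") -> None:
    """Write a cohort in the format :func:`read_cohort` accepts (round-trip safe)."""
    loci = cohort.meta.get("loci", list(LOCI))
    k = max((len(s.pcs) for s in cohort.subjects), default=0)
    any_phase = any(s.phased is not None for s in cohort.subjects)
    rows = []
    for s in cohort.subjects:
        row: dict[str, object] = {
            "id": s.id,
            "phenotype": s.phenotype,
            "sex": s.sex,
            "cohort": s.cohort,
        }
        for j in range(k):
            row[f"pc{j + 1}"] = repr(float(s.pcs[j]))
        for L in loci:
            a, b = s.calls(L)
            row[f"{L}_1"] = "" if a.missing else a.name
            row[f"{L}_2"] = "" if b.missing else b.name
        row["kir3ds1"] = "" if s.kir3ds1 is None else int(s.kir3ds1)
        if any_phase:
            row["hap1"] = "~".join(s.phased[0]) if s.phased else ""
            row["hap2"] = "~".join(s.phased[1]) if s.phased else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Frequencies and filtering
# ---------------------------------------------------------------------------


def allele_frequencies(
    cohort: CohortTable, group: str = "all", loci: Iterable[str] | None = None
) -> dict[str, float]:
    """Allele frequencies over non-missing chromosomes, per locus.

    Returns a flat map ``allele name -> frequency``; within each locus the
    frequencies sum to 1 over the observed alleles.  Missing calls are
    excluded from the denominator (two chromosomes per typed subject) and
    the excluded count is logged.
    """
    sub = cohort.group(group)
    if len(sub) == 0:
        raise ValueError(f"group {group!r} is empty")
    loci = list(loci) if loci is not None else list(cohort.meta.get("loci", LOCI))
    freqs: dict[str, float] = {}
    for L in loci:
        counts: dict[str, int] = {}
        n_missing = 0
        for s in sub:
            for call in s.calls(L):
                if call.missing:
                    n_missing += 1
                else:
                    counts[call.name] = counts.get(call.name, 0) + 1
        total = sum(counts.values())
        if n_missing:
            logger.info("locus %s (%s): %d missing chromosomes excluded", L, group, n_missing)
        for name, c in counts.items():
            freqs[name] = c / total
    return freqs


def maf_filter(freqs: Mapping[str, float], threshold: float = 0.01) -> set[str]:
    """Alleles with frequency strictly greater than ``threshold``.

    ``freqs`` must be control-group frequencies: the filter is defined on
    controls only, never on cases.  Boundary alleles (exactly at the
    threshold) are excluded.
    """
    if not (0.0 < threshold < 0.5):
        raise ValueError(f"threshold must be in (0, 0.5), got {threshold}")
    return {a for a, f in freqs.items() if f > threshold}


def carrier_frequency(cohort: CohortTable, allele: str, group: str = "all") -> float:
    """Dominant-model carrier frequency among subjects typed at the locus."""
    sub = cohort.group(group)
    flags = [s.carries(allele) for s in sub]
    known = [f for f in flags if f is not None]
    if not known:
        raise ValueError(f"no subject typed at the locus of {allele}")
    return sum(known) / len(known)
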