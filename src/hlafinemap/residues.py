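"""Translate classical alleles into per-position amino-acid dosages.

Because the protein sequence of an HLA molecule is fully determined by its
four-digit (two-field) allele name, every subject's residue content at an
aligned position can be read off a positional residue table.  A subject's
additive dosage for (position, residue) is the number of their two alleles
carrying that residue — the coding under which residue-level association
tests are run.

Positions use 1-based mature-protein coordinates (62, 67, 70, 80, 97, 116,
156...); the alignment file's header row is the single source of truth for
the convention.  Gap (``-``) and unknown (``?``) symbols are treated as
missing at that position, never as a residue level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import AlleleCall, CohortTable

logger = logging.getLogger("hlafinemap")

GAP_SYMBOLS = frozenset({"-", "?", "*", "."})


@dataclass
class ProteinAlignment:
    """Allele → positional residue map for one or more loci.

    ``positions[locus]`` is the ordered list of 1-based mature-protein
    positions; ``residues[allele]`` the same-length residue string.  All
    alleles at a locus share the aligned length.
    """

    positions: dict[str, list[int]]
    residues: dict[str, str]

    def __post_init__(self) -> None:
        for allele, seq in self.residues.items():
            locus = allele.split("*")[0]
            if locus not in self.positions:
                raise ValueError(f"alignment has allele {allele} but no positions for {locus}")
            if len(seq) != len(self.positions[locus]):
                raise ValueError(
                    f"{allele}: {len(seq)} residues for {len(self.positions[locus])} positions"
                )

    def loci(self) -> list[str]:
        return sorted(self.positions)

    def residue_at(self, allele: str, position: int) -> str | None:
        """Residue of ``allele`` at ``position``; None if the allele or
        position is absent, or the symbol is a gap/unknown."""
        seq = self.residues.get(allele)
        if seq is None:
            return None
        locus = allele.split("*")[0]
        try:
            ix = self.positions[locus].index(position)
        except ValueError:
            return None
        sym = seq[ix]
        return None if sym in GAP_SYMBOLS else sym


def load_alignment(path: str | Path) -> ProteinAlignment:
    """Load a TSV alignment: column ``allele`` then one column per position
    (integer headers).  One file may mix loci; positions absent for a locus
    are marked ``?`` in its rows."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").set_index("allele")
    cols = [int(c) for c in df.columns]
    positions: dict[str, list[int]] = {}
    residues: dict[str, str] = {}
    for allele, row in df.iterrows():
        locus = str(allele).split("*")[0]
        positions.setdefault(locus, cols)
        residues[str(allele)] = "".join(str(v) for v in row.values)
    return ProteinAlignment(positions, residues)


def default_alignment() -> ProteinAlignment:
    """The packaged alignment fixture (alleles named in the source study;
    see the file's provenance header — partly synthetic)."""
    from importlib.resources import files

    return load_alignment(files("hlafinemap") / "data" / "alignment_synthetic.tsv")


@dataclass
class ResidueDosageMatrix:
    """Subjects × (locus, position, residue) additive dosage matrix.

    ``dosage`` is a float DataFrame (0/1/2, NaN = missing) indexed by
    subject id with a ``(locus, position, residue)`` MultiIndex on columns.
    For a subject typed at both chromosomes of a locus, dosages at any
    position sum to 2 across residues (gaps excepted).
    """

    dosage: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def column(self, locus: str, position: int, residue: str) -> pd.Series:
        key = (locus, position, residue)
        if key not in self.dosage.columns:
            near = [
                r for (L, p, r) in self.dosage.columns if L == locus and p == position
            ]
            raise KeyError(
                f"no column for {locus} position {position} residue {residue}; "
                f"residues present at that position: {sorted(near) or 'none'}"
            )
        s = self.dosage[key]
        s.name = f"{locus}_{position}{residue}"
        return s

    def position_columns(self, locus: str, position: int) -> pd.DataFrame:
        cols = [c for c in self.dosage.columns if c[0] == locus and c[1] == position]
        return self.dosage[cols]


def expand_residues(
    cohort: CohortTable,
    alignment: ProteinAlignment,
    loci: list[str] | None = None,
    control_freq_threshold: float = 0.01,
) -> ResidueDosageMatrix:
    """Expand allele calls into a residue dosage matrix.

    One column is kept per observed (locus, position, residue) whose
    control-group minor frequency min(f, 1-f) strictly exceeds
    ``control_freq_threshold`` — the >1%-in-controls rule applied to
    classical alleles, extended so near-fixed residues are dropped too.
    Alleles sharing a protein sequence naturally collapse into the same
    columns, so identical (position, residue) labels never repeat.

    Subjects whose allele is absent from the alignment get missing dosages
    at that locus (a warning is logged); a gap-coded allele contributes
    nothing at the gapped position and the other allele is counted alone.
    """
    loci = loci or [L for L in alignment.loci()]
    is_control = np.array([s.phenotype == "control" for s in cohort.subjects])
    unknown_alleles: set[str] = set()

    # residue content per subject chromosome, position-wise
    frames: dict[tuple[str, int, str], np.ndarray] = {}
    chrom_known: dict[tuple[str, int], np.ndarray] = {}
    for L in loci:
        positions = alignment.positions.get(L, [])
        for pos in positions:
            # map allele -> residue once per position
            seen: dict[tuple[str, int, str], np.ndarray] = {}
            n_known = np.zeros(len(cohort), dtype=float)
            for i, s in enumerate(cohort.subjects):
                for call in s.calls(L):
                    if call.missing:
                        continue
                    if call.name not in alignment.residues:
                        unknown_alleles.add(call.name)
                        continue
                    res = alignment.residue_at(call.name, pos)
                    if res is None:
                        continue
                    key = (L, pos, res)
                    if key not in seen:
                        seen[key] = np.zeros(len(cohort), dtype=float)
                    seen[key][i] += 1.0
                    n_known[i] += 1.0
            chrom_known[(L, pos)] = n_known
            frames.update(seen)
    if unknown_alleles:
        logger.warning(
            "alleles absent from alignment, dosages set missing: %s",
            ", ".join(sorted(unknown_alleles)),
        )

    keep: dict[tuple[str, int, str], np.ndarray] = {}
    for key, vec in frames.items():
        known = chrom_known[(key[0], key[1])]
        ctrl_chroms = known[is_control].sum()
        if ctrl_chroms <= 0:
            continue
        ctrl_freq = vec[is_control].sum() / ctrl_chroms
        # minor-allele rule: a residue carried by (almost) every control
        # chromosome is no variant either
        if min(ctrl_freq, 1.0 - ctrl_freq) > control_freq_threshold:
            keep[key] = vec

    data = {}
    for key in sorted(keep):
        vec = keep[key].copy()
        known = chrom_known[(key[0], key[1])]
        vec[known == 0] = np.nan  # untyped / unknown-allele subjects
        data[key] = vec
    df = pd.DataFrame(data, index=cohort.ids)
    if data:
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=["locus", "position", "residue"])
    else:
        df.columns = pd.MultiIndex.from_tuples([], names=["locus", "position", "residue"])
    meta = {
        "chromosomes_known": chrom_known,
        "unknown_alleles": sorted(unknown_alleles),
        "control_freq_threshold": control_freq_threshold,
    }
    return ResidueDosageMatrix(df, meta)


def marker_residue(
    matrix: ResidueDosageMatrix, locus: str, position: int, residue: str
) -> pd.Series:
    """Per-subject additive dosage of one residue (e.g. Tyr116 → ``(B,116,'Y')``),
    usable directly as an association term."""
    return matrix.column(locus, position, residue)


# ---------------------------------------------------------------------------
# Serological epitopes and named allele groups
# ---------------------------------------------------------------------------

#: HLA-B position defining the Bw4/Bw6 serological epitopes.
BW_POSITION = 80

_BW_CLASSES = {"I": "Bw4_80I", "T": "Bw4_80T", "N": "Bw6"}


def classify_bw(allele: AlleleCall | str, alignment: ProteinAlignment) -> str:
    """Bw4/Bw6 epitope class of an HLA-B allele from its position-80 residue.

    Isoleucine → ``Bw4_80I``, threonine → ``Bw4_80T``, asparagine → ``Bw6``;
    anything else (including alleles absent from the alignment) → ``unknown``.
    Only Bw4 epitopes serve as KIR3DS1/3DL1 ligands, 80I with the higher
    receptor affinity.
    """
    name = allele if isinstance(allele, str) else allele.name
    if not name.startswith("B*"):
        raise ValueError(f"Bw4/Bw6 classification applies to HLA-B alleles, got {name!r}")
    res = alignment.residue_at(name, BW_POSITION)
    return _BW_CLASSES.get(res or "", "unknown")


def load_allele_groups(path: str | Path | None = None) -> dict[str, list[str]]:
    """Named allele groups (YAML name → allele list).  The packaged default
    defines the B*35 Px/PY peptide-binding groups."""
    if path is None:
        from importlib.resources import files

        path = files("hlafinemap") / "data" / "allele_groups.yaml"
    with open(str(path)) as fh:
        groups = yaml.safe_load(fh)
    seen: dict[str, str] = {}
    for gname, alleles in groups.items():
        for a in alleles:
            if a in seen:
                raise ValueError(f"allele {a} appears in groups {seen[a]!r} and {gname!r}")
            seen[a] = gname
    return groups


def allele_group(
    allele: AlleleCall | str, groups: Mapping[str, list[str]]
) -> str | None:
    """First named group containing the allele, or None."""
    name = allele if isinstance(allele, str) else allele.name
    for gname, alleles in groups.items():
        if name in alleles:
            return gname
    return None
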