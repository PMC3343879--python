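"""Impute rs67384697 (HLA-C 3'UTR G/del) from four-digit HLA-C alleles.

The G/deletion polymorphism in the HLA-C 3' untranslated region controls
microRNA hsa-miR-148 binding and thereby HLA-C surface expression (the
deletion escapes repression).  Because specific HLA-C classical alleles are
in near-perfect LD with one or the other state, the genotype can be read
off a per-allele lookup table: the imputed dosage is the number of a
subject's two HLA-C alleles that map to ``del``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .association import AssociationResult, fit_logistic
from .cohort import CohortTable

logger = logging.getLogger("hlafinemap")

STATES = ("G", "del", "unknown")


@dataclass
class DeletionMap:
    """HLA-C allele → rs67384697 state lookup with provenance."""

    mapping: dict[str, str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("deletion map is empty")
        bad = {a: s for a, s in self.mapping.items() if s not in STATES}
        if bad:
            raise ValueError(f"invalid deletion states: {bad}")

    def state(self, allele: str) -> str:
        return self.mapping.get(allele, "unknown")


def load_deletion_map(path: str | Path | None = None) -> DeletionMap:
    """Load a two-column TSV (allele, state).  Without a path, the packaged
    synthetic default is used (C*06:02→del is grounded in reported LD; the
    rest are test defaults)."""
    if path is None:
        from importlib.resources import files

        path = files("hlafinemap") / "data" / "deletion_map_synthetic.tsv"
        prov = "packaged synthetic default"
    else:
        prov = str(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return DeletionMap(dict(zip(df["allele"], df["state"])), provenance=prov)


def impute_deletion(cohort: CohortTable, dmap: DeletionMap) -> pd.Series:
    """Per-subject rs67384697 del dosage (0/1/2; NaN when not imputable).

    A subject with any HLA-C allele mapping to ``unknown`` (or any missing
    call) gets a missing genotype; the count is logged.  Pure in the map
    and the subject's HLA-C calls only.
    """
    out = []
    n_missing = 0
    for s in cohort:
        a, b = s.calls("C")
        if a.missing or b.missing:
            out.append(np.nan)
            n_missing += 1
            continue
        states = [dmap.state(a.name), dmap.state(b.name)]
        if "unknown" in states:
            out.append(np.nan)
            n_missing += 1
        else:
            out.append(float(states.count("del")))
    if n_missing:
        logger.info("impute_deletion: %d subjects not imputable", n_missing)
    return pd.Series(out, index=cohort.ids, name="rs67384697_del")


def deletion_association(
    cohort: CohortTable,
    dmap: DeletionMap | None = None,
    covariates: pd.DataFrame | None = None,
    condition: list | None = None,
) -> AssociationResult:
    """Additive association of the imputed del dosage with case status,
    optionally conditional on classical-allele dosages (e.g. the top HLA-C
    allele, to ask whether the expression variant carries signal beyond it)."""
    dmap = dmap or load_deletion_map()
    dosage = impute_deletion(cohort, dmap)
    return fit_logistic(cohort.phenotype, dosage, covariates=covariates, condition=condition)
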