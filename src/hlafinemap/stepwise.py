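"""Forward stepwise selection of independently associated terms.

Starting from an empty model (or a forced seed term such as the strongest
single-allele signal), every unselected candidate is tested conditional on
all previously selected terms; the smallest conditional Wald p enters if it
beats the Bonferroni stopping threshold, and the loop stops otherwise.
There is no backward elimination.  The final model is refit jointly so each
selected term also gets a multivariate effect estimate.

The stopping thresholds used in the source analyses ship as constants:
0.05/88 class I+II candidate alleles, 0.05/52 class I candidate alleles and
0.05/480 residue columns, i.e. Bonferroni corrections for the respective
candidate counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import AssociationResult, fit_logistic

logger = logging.getLogger("hlafinemap")

#: Bonferroni stopping thresholds (0.05 / number of candidates).
THRESHOLD_CLASS_I_II = 0.0006  # 88 class I + class II alleles
THRESHOLD_CLASS_I = 0.00096  # 52 class I alleles
THRESHOLD_RESIDUES = 0.0001  # 480 amino-acid residue columns


@dataclass
class StepwiseTrace:
    """Selection history plus the joint refit of the final model."""

    steps: list[tuple[str, AssociationResult]]
    final: list[AssociationResult]
    threshold: float
    n_candidates: int
    stopped_because: str = ""

    @property
    def selected(self) -> list[str]:
        return [t for t, _ in self.steps]

    def as_frame(self) -> pd.DataFrame:
        """Table mirroring the stepwise-univariate / multivariate layout."""
        multi = {r.term: r for r in self.final}
        rows = []
        for term, entry in self.steps:
            m = multi.get(term)
            rows.append(
                {
                    "term": term,
                    "stepwise_p": entry.p,
                    "stepwise_OR": entry.or_,
                    "multivariate_p": m.p if m else np.nan,
                    "multivariate_OR": m.or_ if m else np.nan,
                }
            )
        return pd.DataFrame(rows)


def _adds_rank(cand: pd.Series, selected_vecs: list[pd.Series]) -> bool:
    """True unless the candidate is linearly dependent on the constant and
    the already-selected terms (the aliasing guard: a duplicate of a
    selected term must never re-enter as an 'independent' effect)."""
    cols = [np.ones(len(cand))] + [np.asarray(v, dtype=float) for v in selected_vecs]
    base = np.column_stack(cols)
    cv = np.asarray(cand, dtype=float)
    mask = np.isfinite(base).all(axis=1) & np.isfinite(cv)
    base, cv = base[mask], cv[mask]
    return np.linalg.matrix_rank(np.column_stack([base, cv])) > np.linalg.matrix_rank(base)


def stepwise_select(
    y,
    candidates: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    threshold: float = THRESHOLD_CLASS_I_II,
    seed_term: str | None = None,
) -> StepwiseTrace:
    """Forward stepwise selection over candidate dosage columns.

    ``seed_term`` forces a first entry (its unconditional fit is recorded as
    its entry result) — the workflow of conditioning everything on the top
    allele first.  Ties at entry break by larger |beta|, then term name.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    cand_names = [str(c) for c in candidates.columns]
    candidates = candidates.copy()
    candidates.columns = cand_names
    if seed_term is not None and seed_term not in cand_names:
        raise ValueError(f"seed term {seed_term!r} is not a candidate")

    steps: list[tuple[str, AssociationResult]] = []
    selected: list[str] = []
    stopped = ""

    if seed_term is not None:
        res = fit_logistic(y, candidates[seed_term], covariates=covariates)
        steps.append((seed_term, res))
        selected.append(seed_term)

    while True:
        remaining = [c for c in cand_names if c not in selected]
        if not remaining:
            stopped = "candidates exhausted"
            break
        sel_vecs = [candidates[t] for t in selected]
        best: AssociationResult | None = None
        for name in remaining:
            if not _adds_rank(candidates[name], sel_vecs):
                logger.debug("stepwise: candidate %s aliased with selected terms", name)
                continue
            try:
                res = fit_logistic(y, candidates[name], covariates=covariates, condition=sel_vecs)
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.debug("stepwise: candidate %s skipped: %s", name, exc)
                continue
            if res.unstable:
                logger.debug("stepwise: candidate %s unstable, skipped", name)
                continue
            if best is None or (res.p, -abs(res.beta), res.term) < (
                best.p,
                -abs(best.beta),
                best.term,
            ):
                best = res
        if best is None:
            stopped = "no fittable candidate"
            break
        if not (best.p < threshold):
            stopped = f"min entry p {best.p:.3g} >= threshold {threshold:g}"
            break
        steps.append((best.term, best))
        selected.append(best.term)

    final: list[AssociationResult] = []
    for term in selected:
        others = [candidates[t] for t in selected if t != term]
        try:
            final.append(fit_logistic(y, candidates[term], covariates=covariates, condition=others))
        except (ValueError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            logger.warning("stepwise: joint refit failed for %s: %s", term, exc)
    return StepwiseTrace(
        steps=steps,
        final=final,
        threshold=threshold,
        n_candidates=len(cand_names),
        stopped_because=stopped,
    )


def residual_signal_test(
    y,
    focal,
    conditioning: list,
    covariates: pd.DataFrame | None = None,
) -> AssociationResult:
    """Association of a focal term conditional on a set of other terms.

    The residual-effect workflow: e.g. testing whether an allele retains
    signal after conditioning on all of its own coding residues, or whether
    a class II allele's signal survives conditioning on the top class I
    allele.  The focal term must not itself be in the conditioning set.
    """
    fname = getattr(focal, "name", None)
    for c in conditioning:
        if getattr(c, "name", None) is not None and getattr(c, "name", None) == fname:
            raise ValueError(f"focal term {fname!r} appears in its own conditioning set")
    return fit_logistic(y, focal, covariates=covariates, condition=conditioning)
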