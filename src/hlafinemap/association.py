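"""Covariate-adjusted association testing for alleles, residues and markers.

Single terms are tested with an additive (0/1/2 dosage) logistic regression
and a Wald test, adjusting for sex, cohort and ancestry principal
components; conditioning on previously selected terms is implemented by
adding their dosages as covariates.  Multi-residue positions get a single
omnibus p-value from a likelihood-ratio test of all residue levels jointly
(one reference level dropped).  Cross-cohort consistency is summarised by
fixed-effect inverse-variance pooling with Cochran's Q and the I²
heterogeneity index.

Model fitting is delegated to statsmodels (Newton-Raphson, relative
tolerance 1e-10, 100 iterations max); quasi-separated fits are detected
after the fact — any |log-OR| above ``SEPARATION_BETA`` or a non-converged
optimiser marks the result unstable rather than reporting a spurious
p-value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

logger = logging.getLogger("hlafinemap")

#: |beta| beyond which a fit is flagged as (quasi-)separated.
SEPARATION_BETA = 15.0
_FIT_KW = dict(method="newton", tol=1e-10, maxiter=100, disp=0)


@dataclass
class AssociationResult:
    """One additive association test: effect, OR, CI, Wald p."""

    term: str
    beta: float
    se: float
    or_: float
    ci95: tuple[float, float]
    p: float
    n_cases: int
    n_controls: int
    conditioned_on: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    converged: bool = True
    unstable: bool = False
    note: str = ""

    def as_dict(self) -> dict:
        d = {
            "term": self.term,
            "beta": self.beta,
            "se": self.se,
            "OR": self.or_,
            "ci_lo": self.ci95[0],
            "ci_hi": self.ci95[1],
            "p": self.p,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "conditioned_on": ",".join(self.conditioned_on),
            "unstable": self.unstable,
        }
        return d


class AliasingWarning(UserWarning):
    """A conditioning/covariate column was dropped as collinear."""


def _drop_aliased(X: pd.DataFrame, protect: list[str]) -> pd.DataFrame:
    """Drop columns (never the protected ones) until the design is full rank.

    Greedy: later columns are dropped first, so conditioning terms added
    after the focal term lose to it when perfectly collinear.
    """
    X = X.loc[:, [c for c in X.columns if X[c].std() > 0 or c == "const"]]
    while True:
        rank = np.linalg.matrix_rank(X.values)
        if rank == X.shape[1]:
            return X
        dropped = False
        for col in reversed(X.columns):
            if col in protect or col == "const":
                continue
            trial = X.drop(columns=[col])
            if np.linalg.matrix_rank(trial.values) == rank:
                warnings.warn(f"dropping aliased column {col!r}", AliasingWarning, stacklevel=3)
                X = trial
                dropped = True
                break
        if not dropped:  # aliasing involves only protected columns
            return X


def _align(y, x, covariates, condition) -> tuple[np.ndarray, pd.DataFrame, str]:
    """Assemble the design matrix, aligning on a shared index and dropping
    rows with any missing value."""
    x = pd.Series(np.asarray(x, dtype=float)) if not isinstance(x, pd.Series) else x.astype(float)
    term = x.name or "term"
    parts = {term: x}
    if condition:
        for j, c in enumerate(condition):
            c = pd.Series(np.asarray(c, dtype=float), index=x.index) if not isinstance(c, pd.Series) else c
            parts[c.name or f"cond{j}"] = c.astype(float)
    if covariates is not None and len(getattr(covariates, "columns", [])) > 0:
        for c in covariates.columns:
            parts[c] = covariates[c].astype(float)
    X = pd.DataFrame(parts)
    y = pd.Series(np.asarray(y, dtype=float), index=X.index) if not isinstance(y, pd.Series) else y.astype(float)
    mask = X.notna().all(axis=1) & y.notna()
    return y[mask].values, sm.add_constant(X[mask], has_constant="add"), term


def _ridge_logit(y: np.ndarray, X: pd.DataFrame, lam: float = 1e-3, n_iter: int = 200):
    """Ridge-penalised IRLS fallback for separated designs.

    Keeps the fit finite so the result can be reported as unstable instead
    of erroring out mid-scan; the tiny penalty shrinks only the diverging
    directions appreciably."""
    Xv = X.values
    beta = np.zeros(Xv.shape[1])
    for _ in range(n_iter):
        eta = np.clip(Xv @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-10)
        H = (Xv * w[:, None]).T @ Xv + lam * np.eye(Xv.shape[1])
        g = Xv.T @ (y - mu) - lam * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
    cov = np.linalg.inv(H)
    return (
        dict(zip(X.columns, beta)),
        dict(zip(X.columns, np.sqrt(np.maximum(np.diag(cov), 0.0)))),
    )


def fit_logistic(
    y,
    x,
    covariates: pd.DataFrame | None = None,
    condition: list | None = None,
) -> AssociationResult:
    """Additive logistic association of a dosage vector with case status.

    ``y`` is 0/1 (1 = case); ``x`` a 0/1/2 dosage (NaN rows dropped);
    ``condition`` a list of dosage vectors entered as covariates.  Returns
    the Wald test on the focal term.  Aliased covariate/conditioning
    columns are dropped with an :class:`AliasingWarning`; a zero-variance
    focal term is an error; separation flags the result unstable.
    """
    yv, X, term = _align(y, x, covariates, condition)
    if len(np.unique(yv)) < 2:
        raise ValueError("phenotype has a single class after alignment")
    if X[term].std() == 0:
        raise ValueError(f"focal term {term!r} has zero variance")
    X = _drop_aliased(X, protect=[term])

    converged = True
    note = ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels convergence chatter
        try:
            fit = sm.Logit(yv, X).fit(**_FIT_KW)
            converged = bool(fit.mle_retvals.get("converged", True))
            params = {c: float(fit.params[c]) for c in X.columns}
            bses = {c: float(fit.bse[c]) for c in X.columns}
        except Exception:  # singular Hessian under (quasi-)separation
            params, bses = _ridge_logit(yv, X)
            converged = False
            note = "separation: ridge-stabilised fit"

    beta = params[term]
    se = bses.get(term, float("nan"))
    unstable = (not converged) or abs(beta) > SEPARATION_BETA or not np.isfinite(se)
    if unstable and not note:
        note = "unstable fit (possible separation)"
    z = beta / se if se and np.isfinite(se) and se > 0 else np.nan
    p = float(2 * st.norm.sf(abs(z))) if np.isfinite(z) else float("nan")
    p = max(p, np.nextafter(0, 1)) if np.isfinite(p) else p
    half = 1.959963984540054 * se
    return AssociationResult(
        term=term,
        beta=beta,
        se=se,
        or_=float(np.exp(beta)),
        ci95=(float(np.exp(beta - half)), float(np.exp(beta + half))),
        p=p,
        n_cases=int(yv.sum()),
        n_controls=int(len(yv) - yv.sum()),
        conditioned_on=[getattr(c, "name", f"cond{j}") for j, c in enumerate(condition or [])],
        covariates=[c for c in (covariates.columns if covariates is not None else [])],
        converged=converged,
        unstable=bool(unstable),
        note=note,
    )


def omnibus_position_test(
    y, position_columns: pd.DataFrame, covariates: pd.DataFrame | None = None
) -> tuple[float, int]:
    """Single p-value for all residues at one position (LRT, df = k-1).

    Fits covariates-plus-(k-1)-residue-dosages against the covariates-only
    null (one reference residue dropped — the LRT statistic is invariant to
    which, as the k dosage columns are linearly dependent given complete
    calls).  Requires at least two residue columns.
    """
    k = position_columns.shape[1]
    if k < 2:
        raise ValueError("omnibus test needs >=2 residue columns; use fit_logistic for one")
    cols = position_columns.iloc[:, 1:]  # drop reference residue (first)
    parts = [cols]
    if covariates is not None and len(covariates.columns):
        parts.append(covariates)
    X = pd.concat(parts, axis=1)
    X.columns = [str(c) for c in X.columns]
    y = pd.Series(np.asarray(y, dtype=float), index=X.index) if not isinstance(y, pd.Series) else y.astype(float)
    mask = X.notna().all(axis=1) & y.notna()
    yv = y[mask].values
    Xf = sm.add_constant(X[mask], has_constant="add")
    Xf = _drop_aliased(Xf, protect=[])
    res_cols = [c for c in Xf.columns if c in [str(c0) for c0 in cols.columns]]
    Xnull = Xf.drop(columns=res_cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.Logit(yv, Xf).fit(**_FIT_KW)
        null = sm.Logit(yv, Xnull).fit(**_FIT_KW)
    df = len(res_cols)
    lrt = 2.0 * (full.llf - null.llf)
    return float(st.chi2.sf(max(lrt, 0.0), df)), df


def scan(
    y,
    columns: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    condition: list | None = None,
) -> list[AssociationResult]:
    """Test every column; rank by ascending p, ties by descending |beta|
    then term name.  Per-term failures are logged and skipped."""
    results: list[AssociationResult] = []
    for col in columns.columns:
        x = columns[col]
        x.name = str(col) if not isinstance(col, str) else col
        try:
            results.append(fit_logistic(y, x, covariates, condition))
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("scan: term %s failed: %s", col, exc)
    results.sort(key=lambda r: (r.p if np.isfinite(r.p) else np.inf, -abs(r.beta), r.term))
    return results


@dataclass
class HeterogeneityResult:
    """Cochran's Q and I² for one term across cohorts."""

    term: str
    q: float
    df: int
    i2: float  # percent, [0, 100]
    pooled_beta: float
    pooled_se: float
    p_q: float
    betas: list[float]
    ses: list[float]


def heterogeneity(per_cohort: list[tuple[float, float]], term: str = "") -> HeterogeneityResult:
    """Fixed-effect inverse-variance pooling with Cochran's Q and I².

    ``per_cohort`` holds (beta, se) per cohort;  Q = Σ w (beta - pooled)²,
    w = 1/se², and I² = max(0, (Q - df)/Q) × 100 — the percent of
    variation attributable to between-cohort heterogeneity.
    """
    if len(per_cohort) < 2:
        raise ValueError("heterogeneity needs >=2 cohorts (df would be 0)")
    betas = np.array([b for b, _ in per_cohort], dtype=float)
    ses = np.array([s for _, s in per_cohort], dtype=float)
    if not np.all(np.isfinite(betas)) or not np.all(np.isfinite(ses)) or np.any(ses <= 0):
        raise ValueError("all betas and ses must be finite, ses positive")
    w = 1.0 / ses**2
    pooled = float((w * betas).sum() / w.sum())
    q = float((w * (betas - pooled) ** 2).sum())
    df = len(per_cohort) - 1
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityResult(
        term=term,
        q=q,
        df=df,
        i2=i2,
        pooled_beta=pooled,
        pooled_se=float(np.sqrt(1.0 / w.sum())),
        p_q=float(st.chi2.sf(q, df)),
        betas=betas.tolist(),
        ses=ses.tolist(),
    )


def results_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Flatten results for TSV export (term, p, OR, CI, conditioning set)."""
    return pd.DataFrame([r.as_dict() for r in results])
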