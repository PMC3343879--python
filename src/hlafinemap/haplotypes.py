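"""EM haplotype-frequency estimation, case/control haplotype tests, LD.

Unphased multi-locus genotypes are phase-ambiguous whenever a subject is
heterozygous at two or more loci.  Under Hardy-Weinberg equilibrium the
classic genotype EM resolves this: the E-step distributes each subject's
genotype over its compatible ordered haplotype pairs in proportion to the
current frequency products, the M-step re-estimates frequencies from the
expected haplotype counts.  The observed-data log-likelihood is
non-decreasing every iteration; perturbed restarts guard against the rare
non-global stationary point.

Cases and controls are estimated separately (running jointly would bias
the frequencies under association), and group differences are tested on a
2×2 table of estimated haplotype counts — chi-square by default, exact
test when any expected cell is small.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.stats as st

from .cohort import CohortTable

logger = logging.getLogger("hlafinemap")

Haplotype = tuple[str, ...]


@dataclass
class HaplotypeFrequencyEstimate:
    """EM-estimated haplotype frequencies and the log-likelihood trace."""

    loci: tuple[str, ...]
    freqs: dict[Haplotype, float]
    loglik: float
    n_iter: int
    converged: bool
    n_chromosomes: int
    loglik_trace: list[float] = field(default_factory=list)

    def frequency(self, haplotype: Haplotype) -> float:
        return self.freqs.get(tuple(haplotype), 0.0)


def _genotype_classes(cohort: CohortTable, loci: list[str]):
    """Collapse subjects into distinct unordered multi-locus genotypes.

    Returns (classes, counts, n_excluded): each class is a tuple of
    per-locus unordered allele pairs; subjects missing any call at the
    requested loci are excluded.
    """
    counts: dict[tuple, int] = {}
    n_excluded = 0
    for s in cohort:
        geno = []
        ok = True
        for L in loci:
            a, b = s.calls(L)
            if a.missing or b.missing:
                ok = False
                break
            geno.append(tuple(sorted((a.name, b.name))))
        if not ok:
            n_excluded += 1
            continue
        key = tuple(geno)
        counts[key] = counts.get(key, 0) + 1
    return list(counts), np.array([counts[k] for k in counts], dtype=float), n_excluded


def _expand_pairs(genotype) -> list[tuple[Haplotype, Haplotype]]:
    """All distinct unordered haplotype pairs compatible with a genotype."""
    het = [i for i, (a, b) in enumerate(genotype) if a != b]
    pairs = set()
    # fix the first heterozygous locus to kill the global phase flip
    choices = [(0,)] + [(0, 1)] * max(0, len(het) - 1)
    for flips in itertools.product(*choices) if het else [()]:
        h1, h2 = [], []
        fi = 0
        for i, (a, b) in enumerate(genotype):
            if a == b:
                h1.append(a)
                h2.append(b)
            else:
                if flips[fi]:
                    a, b = b, a
                h1.append(a)
                h2.append(b)
                fi += 1
        pairs.add(tuple(sorted((tuple(h1), tuple(h2)))))
    return sorted(pairs)


def em_haplotypes(
    cohort: CohortTable,
    loci: list[str],
    tol: float = 1e-8,
    max_iter: int = 10_000,
    n_restarts: int = 5,
    seed: int = 17,
    prune: float = 1e-6,
) -> HaplotypeFrequencyEstimate:
    """Maximum-likelihood haplotype frequencies by genotype EM under HWE.

    Convergence is declared when the max absolute frequency change drops
    below ``tol``; ``n_restarts`` runs start from Dirichlet-perturbed
    uniform frequencies and the best final log-likelihood wins.
    Deterministic given ``seed``; invariant to subject order.  Haplotypes
    with final frequency below ``prune`` are dropped from the output.
    """
    if not loci:
        raise ValueError("at least one locus required")
    classes, counts, n_excluded = _genotype_classes(cohort, list(loci))
    if not classes:
        raise ValueError("no subject has complete calls at the requested loci")
    if n_excluded:
        logger.info("EM: %d subjects excluded for missing calls at %s", n_excluded, loci)

    # universe of candidate haplotypes = those compatible with some subject
    pair_lists = [_expand_pairs(g) for g in classes]
    hap_ix: dict[Haplotype, int] = {}
    for plist in pair_lists:
        for h1, h2 in plist:
            for h in (h1, h2):
                hap_ix.setdefault(h, len(hap_ix))
    H = len(hap_ix)
    n_chrom = int(2 * counts.sum())

    # flat arrays for vectorised E-steps
    pi1, pi2, pmult, pclass = [], [], [], []
    for ci, plist in enumerate(pair_lists):
        for h1, h2 in plist:
            pi1.append(hap_ix[h1])
            pi2.append(hap_ix[h2])
            pmult.append(1.0 if h1 == h2 else 2.0)
            pclass.append(ci)
    pi1 = np.array(pi1)
    pi2 = np.array(pi2)
    pmult = np.array(pmult)
    pclass = np.array(pclass)
    n_classes = len(classes)

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, int, bool, list[float]] | None = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            f = np.full(H, 1.0 / H)
        else:
            f = rng.dirichlet(np.full(H, 5.0))
        trace: list[float] = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            w = pmult * f[pi1] * f[pi2]  # P(pair | f)
            denom = np.bincount(pclass, weights=w, minlength=n_classes)
            trace.append(float((counts * np.log(np.maximum(denom, 1e-300))).sum()))
            post = w * (counts[pclass] / np.maximum(denom[pclass], 1e-300))
            newf = (
                np.bincount(pi1, weights=post, minlength=H)
                + np.bincount(pi2, weights=post, minlength=H)
            ) / n_chrom
            delta = float(np.abs(newf - f).max())
            f = newf
            if delta < tol:
                converged = True
                break
        w = pmult * f[pi1] * f[pi2]
        denom = np.bincount(pclass, weights=w, minlength=n_classes)
        ll = float((counts * np.log(np.maximum(denom, 1e-300))).sum())
        trace.append(ll)
        if best is None or ll > best[0] + 1e-12:
            best = (ll, f, it, converged, trace)

    ll, f, n_iter, converged, trace = best
    if not converged:
        logger.warning("EM did not converge in %d iterations", max_iter)
    inv = {v: k for k, v in hap_ix.items()}
    freqs = {inv[i]: float(f[i]) for i in range(H) if f[i] >= prune}
    return HaplotypeFrequencyEstimate(
        loci=tuple(loci),
        freqs=freqs,
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        n_chromosomes=n_chrom,
        loglik_trace=trace,
    )


def count_phased(cohort: CohortTable, loci: list[str]) -> dict[Haplotype, float]:
    """Haplotype frequencies by direct counting of known-phase subjects.

    Requires phase annotation (``SubjectRecord.phased``, allele names
    ordered like the cohort's generation-time locus list) and serves as the
    phase-certain cross-check of the EM estimate.
    """
    if not loci:
        raise ValueError("at least one locus required")
    order = cohort.meta.get("phase_loci")
    counts: dict[Haplotype, int] = {}
    total = 0
    for s in cohort:
        if s.phased is None:
            raise ValueError(f"subject {s.id} has no phase annotation")
        src = order or [a.split("*")[0] for a in s.phased[0]]
        ix = [src.index(L) for L in loci]
        for hap in s.phased:
            key = tuple(hap[i] for i in ix)
            counts[key] = counts.get(key, 0) + 1
            total += 1
    return {h: c / total for h, c in counts.items()}


def haplotype_case_control_test(
    est_cases: HaplotypeFrequencyEstimate,
    est_controls: HaplotypeFrequencyEstimate,
    haplotype: Haplotype,
) -> dict:
    """Case/control difference for one haplotype from estimated counts.

    Builds a 2×2 table of rounded haplotype chromosome counts (frequency ×
    2N, half-up) against all other haplotypes; chi-square without
    continuity correction by default, exact test when any expected count is
    below 5; odds ratio from the same table (Haldane 0.5 on zero cells).
    """
    if est_cases.loci != est_controls.loci:
        raise ValueError("case and control estimates cover different loci")
    haplotype = tuple(haplotype)
    fc, fn = est_cases.frequency(haplotype), est_controls.frequency(haplotype)
    if fc == 0.0 and fn == 0.0:
        raise ValueError(f"haplotype {haplotype} absent from both groups")
    a = math.floor(fc * est_cases.n_chromosomes + 0.5)
    c = math.floor(fn * est_controls.n_chromosomes + 0.5)
    b = est_cases.n_chromosomes - a
    d = est_controls.n_chromosomes - c
    table = np.array([[a, b], [c, d]], dtype=float)
    expected = st.contingency.expected_freq(table) if table.sum() else table
    if (expected < 5).any():
        from .compound import ContingencyTable2x2, fisher_exact

        p = fisher_exact(ContingencyTable2x2(a, b, c, d))
        method = "fisher"
    else:
        chi2, p, _, _ = st.chi2_contingency(table, correction=False)
        method = "chi2"
    aa, bb, cc, dd = (x + 0.5 if min(a, b, c, d) == 0 else x for x in (a, b, c, d))
    return {
        "haplotype": haplotype,
        "freq_cases": fc,
        "freq_controls": fn,
        "counts": (a, b, c, d),
        "p": float(p),
        "OR": (aa * dd) / (bb * cc),
        "method": method,
    }


@dataclass
class LDStats:
    """Pairwise linkage disequilibrium between two biallelic loci."""

    allele_a: str
    allele_b: str
    d: float
    d_prime: float  # |D'| in [0, 1]
    r2: float


def ld_pair(freqs: dict[tuple[str, str], float]) -> LDStats:
    """D, |D′| and r² from a biallelic×biallelic haplotype frequency table.

    ``freqs`` maps the four (allele_at_locus1, allele_at_locus2) haplotypes
    to frequencies summing to 1.  D = p_AB − p_A·p_B; D′ = D/D_max with the
    standard sign-dependent bound; r² = D² / (p_A p_a p_B p_b).  |D′| = 1
    whenever one haplotype class has frequency 0.
    """
    if abs(sum(freqs.values()) - 1.0) > 1e-6:
        raise ValueError("haplotype frequencies must sum to 1")
    a_alleles = sorted({k[0] for k in freqs})
    b_alleles = sorted({k[1] for k in freqs})
    if len(a_alleles) != 2 or len(b_alleles) != 2:
        raise ValueError("ld_pair requires exactly two alleles at each locus")
    A, a = a_alleles
    B, b = b_alleles
    pAB = freqs.get((A, B), 0.0)
    pA = pAB + freqs.get((A, b), 0.0)
    pB = pAB + freqs.get((a, B), 0.0)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("monomorphic locus: LD undefined")
    D = pAB - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = abs(D) / dmax if dmax > 0 else 0.0
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return LDStats(allele_a=A, allele_b=B, d=float(D), d_prime=float(d_prime), r2=float(r2))
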