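"""End-to-end orchestration: filter → scans → stepwise → haplotypes →
deletion → compound genotype → heterogeneity, with reproducible TSV/JSON
outputs.

Stages run in the order the analysis reads: control-frequency filtering of
classical alleles, the allele scan, residue expansion and scan, omnibus
position tests, forward stepwise selection, haplotype EM with case/control
tests, rs67384697 imputation and conditional analysis, the KIR compound
genotype table, and per-cohort heterogeneity.  A run manifest records the
seed, a config hash and all exclusion counts; identical config and input
give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import fit_logistic, heterogeneity, omnibus_position_test, results_table, scan
from .cohort import CohortTable, allele_frequencies, maf_filter, read_cohort
from .compound import (
    carrier_table,
    fisher_exact,
    odds_ratio,
    predicate_bw4_80i,
    predicate_compound,
    predicate_kir,
)
from .deletion import deletion_association, impute_deletion, load_deletion_map
from .haplotypes import em_haplotypes, haplotype_case_control_test
from .residues import default_alignment, expand_residues, load_alignment
from .stepwise import stepwise_select
from .deletion import DeletionMap

logger = logging.getLogger("hlafinemap")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.  Thresholds are proportions/p-values."""

    cohort_path: str
    out_dir: str
    alignment_path: str | None = None
    deletion_map_path: str | None = None
    loci: tuple[str, ...] = ("A", "B", "C", "DQA1", "DQB1", "DRB1")
    maf_threshold: float = 0.01
    n_pcs: int | None = None
    stepwise_threshold: float = 0.0006
    stepwise_seed_term: str | None = None
    haplotype_loci: tuple[str, ...] = ("B", "C")
    stages: tuple[str, ...] = (
        "scan",
        "residues",
        "stepwise",
        "haplotypes",
        "deletion",
        "compound",
        "heterogeneity",
    )
    seed: int = 42
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not Path(self.cohort_path).exists():
            raise FileNotFoundError(f"cohort file not found: {self.cohort_path}")
        for p in (self.alignment_path, self.deletion_map_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        for t in (self.maf_threshold, self.stepwise_threshold):
            if not (0.0 < t < 1.0):
                raise ValueError(f"threshold {t} outside (0, 1)")

    def digest(self) -> str:
        payload = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _candidate_frame(cohort: CohortTable, alleles: list[str]) -> pd.DataFrame:
    return pd.DataFrame({a: cohort.allele_dosage(a) for a in sorted(alleles)})


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    Per-stage TSVs land in ``out_dir``; a failure aborts with the stage
    name while partial outputs are kept and flagged in the manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    cohort = read_cohort(config.cohort_path)
    alignment = (
        load_alignment(config.alignment_path) if config.alignment_path else default_alignment()
    )
    dmap = load_deletion_map(config.deletion_map_path)
    covars = cohort.covariate_frame(config.n_pcs)
    y = cohort.phenotype

    manifest: dict = {
        "version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_subjects": len(cohort),
        "n_cases": cohort.n_cases(),
        "n_controls": cohort.n_controls(),
        "stages_done": [],
        "exclusions": {},
        "failed_stage": None,
    }

    ctrl_freqs = allele_frequencies(cohort, "controls", loci=config.loci)
    retained = sorted(maf_filter(ctrl_freqs, config.maf_threshold))
    manifest["n_alleles_retained"] = len(retained)
    manifest["exclusions"]["alleles_below_maf"] = len(ctrl_freqs) - len(retained)

    stage = None
    try:
        if "scan" in config.stages:
            stage = "scan"
            cand = _candidate_frame(cohort, retained)
            results = scan(y, cand, covariates=covars)
            case_freqs = allele_frequencies(cohort, "cases", loci=config.loci)
            tab = results_table(results)
            tab.insert(1, "freq_cases", [case_freqs.get(t, 0.0) for t in tab["term"]])
            tab.insert(2, "freq_controls", [ctrl_freqs.get(t, 0.0) for t in tab["term"]])
            tab.to_csv(out / "allele_scan.tsv", sep="\t", index=False)
            manifest["stages_done"].append(stage)

        matrix = None
        if "residues" in config.stages:
            stage = "residues"
            matrix = expand_residues(
                cohort, alignment, loci=[L for L in config.loci if L in alignment.positions],
                control_freq_threshold=config.maf_threshold,
            )
            res_results = scan(y, matrix.dosage, covariates=covars)
            results_table(res_results).to_csv(out / "residue_scan.tsv", sep="\t", index=False)
            omni_rows = []
            positions = sorted({(L, p) for (L, p, _) in matrix.dosage.columns})
            for L, p in positions:
                cols = matrix.position_columns(L, p)
                if cols.shape[1] < 2:
                    continue
                pval, df = omnibus_position_test(y, cols, covars)
                omni_rows.append({"locus": L, "position": p, "df": df, "p": pval})
            pd.DataFrame(omni_rows).to_csv(out / "omnibus_positions.tsv", sep="\t", index=False)
            manifest["stages_done"].append(stage)

        if "stepwise" in config.stages:
            stage = "stepwise"
            cand = _candidate_frame(cohort, retained)
            trace = stepwise_select(
                y,
                cand,
                covariates=covars,
                threshold=config.stepwise_threshold,
                seed_term=config.stepwise_seed_term,
            )
            trace.as_frame().to_csv(out / "stepwise.tsv", sep="\t", index=False)
            manifest["stepwise_selected"] = trace.selected
            manifest["stages_done"].append(stage)

        if "haplotypes" in config.stages:
            stage = "haplotypes"
            hloci = [L for L in config.haplotype_loci]
            est_ca = em_haplotypes(cohort.group("cases"), hloci, seed=config.seed)
            est_co = em_haplotypes(cohort.group("controls"), hloci, seed=config.seed)
            rows = []
            for hap in sorted(set(est_ca.freqs) | set(est_co.freqs)):
                r = haplotype_case_control_test(est_ca, est_co, hap)
                row = {f"{L}": hap[i] for i, L in enumerate(hloci)}
                row.update(
                    freq_cases=r["freq_cases"],
                    freq_controls=r["freq_controls"],
                    p=r["p"],
                    OR=r["OR"],
                    method=r["method"],
                )
                rows.append(row)
            pd.DataFrame(rows).sort_values("p").to_csv(
                out / "haplotypes.tsv", sep="\t", index=False
            )
            manifest["stages_done"].append(stage)

        if "deletion" in config.stages:
            stage = "deletion"
            dosage = impute_deletion(cohort, dmap)
            manifest["exclusions"]["deletion_not_imputable"] = int(dosage.isna().sum())
            rows = []
            res = deletion_association(cohort, dmap, covariates=covars)
            rows.append(dict(res.as_dict(), model="unconditional"))
            for allele in ("C*06:02", "B*57:01"):
                cond = cohort.allele_dosage(allele)
                if cond.notna().any() and cond.std() > 0:
                    res = deletion_association(cohort, dmap, covariates=covars, condition=[cond])
                    rows.append(dict(res.as_dict(), model=f"conditional_on_{allele}"))
            pd.DataFrame(rows).to_csv(out / "deletion.tsv", sep="\t", index=False)
            manifest["stages_done"].append(stage)

        if "compound" in config.stages:
            stage = "compound"
            preds = {
                "KIR3DS1_without_Bw4-80I": predicate_compound(alignment, "kir_only"),
                "Bw4-80I_without_KIR3DS1": predicate_compound(alignment, "bw4_only"),
                "KIR3DS1+Bw4-80I": predicate_compound(alignment, "both"),
                "KIR3DS1": predicate_kir,
                "Bw4-80I": predicate_bw4_80i(alignment),
            }
            rows = []
            for name, pred in preds.items():
                try:
                    t = carrier_table(cohort, pred)
                except ValueError as exc:
                    logger.warning("compound row %s skipped: %s", name, exc)
                    continue
                or_, ci = odds_ratio(t)
                rows.append(
                    {
                        "genetic_variable": name,
                        "freq_cases": f"{t.a}/{t.n_cases}({100 * t.a / t.n_cases:.1f})",
                        "freq_controls": f"{t.c}/{t.n_controls}({100 * t.c / t.n_controls:.1f})",
                        "p": fisher_exact(t),
                        "OR": or_,
                        "ci_lo": ci[0],
                        "ci_hi": ci[1],
                    }
                )
            pd.DataFrame(rows).to_csv(out / "compound_genotype.tsv", sep="\t", index=False)
            manifest["stages_done"].append(stage)

        if "heterogeneity" in config.stages:
            stage = "heterogeneity"
            labels = sorted({s.cohort for s in cohort.subjects})
            rows = []
            if len(labels) >= 2:
                for term in retained:
                    per = []
                    for lab in labels:
                        sub = CohortTable(
                            [s for s in cohort.subjects if s.cohort == lab],
                            dict(cohort.meta),
                        )
                        if sub.n_cases() == 0 or sub.n_controls() == 0:
                            continue
                        x = sub.allele_dosage(term)
                        if not (x.notna().any() and x.std() > 0):
                            continue
                        try:
                            r = fit_logistic(sub.phenotype, x, sub.covariate_frame(config.n_pcs))
                        except (ValueError, np.linalg.LinAlgError):
                            continue
                        if not r.unstable:
                            per.append((r.beta, r.se))
                    if len(per) >= 2:
                        h = heterogeneity(per, term=term)
                        rows.append(
                            {"term": term, "Q": h.q, "df": h.df, "I2": h.i2, "p_Q": h.p_q}
                        )
            pd.DataFrame(rows).to_csv(out / "heterogeneity.tsv", sep="\t", index=False)
            manifest["stages_done"].append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def compare_runs(run_a: str | Path, run_b: str | Path, terms: list[str]) -> dict:
    """Side-by-side OR/p comparison of two runs' allele scans.

    Returns per-term (OR_a, p_a, OR_b, p_b), the list of terms missing from
    either run, and the sign-concordance summary (fraction of compared
    terms whose ORs fall on the same side of 1).
    """
    frames = {}
    for tag, run in (("a", run_a), ("b", run_b)):
        path = Path(run) / "allele_scan.tsv"
        if not path.exists():
            raise FileNotFoundError(path)
        frames[tag] = pd.read_csv(path, sep="\t").set_index("term")
    rows, missing = [], []
    for term in terms:
        if term not in frames["a"].index or term not in frames["b"].index:
            missing.append(term)
            continue
        ra, rb = frames["a"].loc[term], frames["b"].loc[term]
        rows.append(
            {
                "term": term,
                "OR_a": float(ra["OR"]),
                "p_a": float(ra["p"]),
                "OR_b": float(rb["OR"]),
                "p_b": float(rb["p"]),
                "concordant": (ra["OR"] > 1) == (rb["OR"] > 1),
            }
        )
    table = pd.DataFrame(rows)
    concordance = float(table["concordant"].mean()) if len(table) else float("nan")
    return {"table": table, "missing": missing, "concordance": concordance}
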