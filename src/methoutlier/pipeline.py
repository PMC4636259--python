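"""End-to-end orchestration: simulate -> screen -> integrate -> evaluate.

Each stage writes its outputs eagerly so partial runs remain inspectable; the
summary JSON records the candidate funnel (genes in, genes past the score
selection, genes past the correlation filter) along with the seed and a hash
of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Optional

import pandas as pd

from . import diagnostics, integration, screening, simulate
from .datamodel import (
    SampleAnnotation,
    read_annotation,
    read_matrix,
    read_qmsp,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


def _config_hash(config: dict[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def evaluate_assay(
    tissue_df: pd.DataFrame,
    saliva_df: pd.DataFrame,
    annotation: SampleAnnotation,
    genes: Optional[list[str]] = None,
) -> dict[str, Any]:
    """Diagnostic evaluation of quantified QMSP tables.

    tissue_df/saliva_df must carry relative_level and call columns (see
    diagnostics.quantify_qmsp). Returns per-gene and panel DiagnosticSummary
    for saliva (cases vs controls), per-gene tissue detection rates, and
    per-gene tissue-saliva ConcordanceSummary among cases.
    """
    ann = annotation.table
    saliva_patient = ann.loc[ann["specimen"] == "saliva"].set_index("sample_id")
    tissue_patient = ann.loc[ann["specimen"] == "tissue"].set_index("sample_id")

    genes = genes or sorted(saliva_df["gene"].unique())
    sal = saliva_df[saliva_df["gene"].isin(genes)].copy()
    tis = tissue_df[tissue_df["gene"].isin(genes)].copy()
    sal["patient_id"] = sal["sample_id"].map(saliva_patient["patient_id"])
    sal["group"] = sal["sample_id"].map(saliva_patient["group"])
    tis["patient_id"] = tis["sample_id"].map(tissue_patient["patient_id"])

    # wide per-patient call tables; invalid samples (call NA) drop out
    sal_calls = sal.pivot(index="patient_id", columns="gene", values="call")
    sal_levels = sal.pivot(index="patient_id", columns="gene", values="relative_level")
    tis_calls = tis.pivot(index="patient_id", columns="gene", values="call")
    tis_levels = tis.pivot(index="patient_id", columns="gene", values="relative_level")
    disease = (
        sal.drop_duplicates("patient_id").set_index("patient_id")["group"] == "tumor"
    )

    report: dict[str, Any] = {"genes": genes, "saliva": {}, "tissue_detection": {},
                              "concordance": {}}

    def _diag(calls: pd.Series) -> dict[str, Any]:
        ok = calls.notna()
        d = diagnostics.sensitivity_specificity(
            calls[ok].astype(bool).to_numpy(), disease.loc[calls[ok].index].to_numpy()
        )
        return {
            "tp": d.tp, "fp": d.fp, "fn": d.fn, "tn": d.tn,
            "sensitivity_percent": 100 * d.sensitivity,
            "specificity_percent": 100 * d.specificity,
            "se_ci_percent": [100 * d.se_ci[0], 100 * d.se_ci[1]],
            "sp_ci_percent": [100 * d.sp_ci[0], 100 * d.sp_ci[1]],
            "fisher_p": d.fisher_p,
        }

    for gene in genes:
        report["saliva"][gene] = _diag(sal_calls[gene])
    panel_saliva = sal_calls[genes].apply(
        lambda r: diagnostics.panel_combine(r.dropna().astype(bool).tolist())
        if r.notna().any() else pd.NA,
        axis=1,
    )
    report["saliva"]["panel"] = _diag(panel_saliva)

    case_ids = [p for p in tis_calls.index if disease.get(p, False)]
    for gene in genes:
        calls = tis_calls.loc[case_ids, gene].dropna().astype(bool)
        report["tissue_detection"][gene] = {
            "positive": int(calls.sum()),
            "n": int(calls.size),
            "rate_percent": 100.0 * calls.sum() / calls.size if calls.size else None,
        }
    panel_tissue = tis_calls.loc[case_ids, genes].apply(
        lambda r: diagnostics.panel_combine(r.dropna().astype(bool).tolist())
        if r.notna().any() else pd.NA,
        axis=1,
    ).dropna().astype(bool)
    report["tissue_detection"]["panel"] = {
        "positive": int(panel_tissue.sum()),
        "n": int(panel_tissue.size),
        "rate_percent": 100.0 * panel_tissue.sum() / panel_tissue.size
        if panel_tissue.size else None,
    }

    paired = [p for p in case_ids if p in sal_calls.index]
    for gene in genes:
        tc = tis_calls.loc[paired, gene]
        sc = sal_calls.loc[paired, gene]
        ok = tc.notna() & sc.notna()
        summ = diagnostics.concordance_summary(
            tc[ok].astype(bool).to_numpy(),
            sc[ok].astype(bool).to_numpy(),
            tis_levels.loc[paired, gene][ok].to_numpy(),
            sal_levels.loc[paired, gene][ok].to_numpy(),
        )
        report["concordance"][gene] = {
            "a_both_pos": summ.a, "b_saliva_only": summ.b,
            "c_tissue_only": summ.c, "d_both_neg": summ.d,
            "kappa": summ.kappa,
            "kappa_ci": list(summ.kappa_ci) if summ.kappa_ci else None,
            "percent_agreement": summ.percent_agreement,
            "spearman_rho": summ.spearman_rho,
            "spearman_p": summ.spearman_p,
        }
    return report


def run_pipeline(config: dict[str, Any]) -> dict[str, Any]:
    """Run the full pipeline from a config mapping; returns the summary dict.

    Config keys: outdir (required), seed, simulate (cohort/assay parameter
    overrides or false to consume existing inputs), paths (meth/expr/annot/
    qmsp_tissue/qmsp_saliva), screen (OutlierConfig overrides), evaluate
    (genes, curve points). Stage outputs are written as they complete.
    """
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    summary: dict[str, Any] = {
        "seed": seed,
        "config_hash": _config_hash(config),
        "stages": {},
    }

    # --- simulate ---------------------------------------------------------
    paths = dict(config.get("paths", {}))
    if config.get("simulate", True):
        sim_cfg = config.get("simulate") if isinstance(config.get("simulate"), dict) else {}
        cohort = simulate.CohortSpec(seed=seed, **sim_cfg.get("cohort", {}))
        assay = simulate.PairedAssaySpec(seed=seed, **sim_cfg.get("assay", {}))
        datadir = outdir / "data"
        simulate.write_fixture_bundle(datadir, cohort, assay)
        paths.setdefault("meth", datadir / "methylation.tsv")
        paths.setdefault("expr", datadir / "expression.tsv")
        paths.setdefault("annot", datadir / "annotation.tsv")
        paths.setdefault("qmsp_tissue", datadir / "qmsp_tissue.tsv")
        paths.setdefault("qmsp_saliva", datadir / "qmsp_saliva.tsv")
        paths.setdefault("validation_annot", datadir / "validation_annotation.tsv")
        summary["stages"]["simulate"] = {"outdir": str(datadir)}

    # --- screen -----------------------------------------------------------
    try:
        meth = read_matrix(paths["meth"], kind="methylation")
        annot = read_annotation(paths["annot"])
        screen_over = dict(config.get("screen", {}))
        screen_over.setdefault("seed", seed)
        if "score_cutoff" not in screen_over and "top_k" not in screen_over:
            screen_over["top_k"] = int(config.get("top_k", 50))
        ocfg = screening.OutlierConfig(**screen_over)
        results = screening.screen_genes(meth, annot, ocfg)
        selected = screening.select_candidates(results, ocfg)
        screening.results_to_frame(results).to_csv(
            outdir / "screen_all.tsv", sep="\t", index=False, lineterminator="\n")
        screening.results_to_frame(selected).to_csv(
            outdir / "screen_selected.tsv", sep="\t", index=False, lineterminator="\n")
        summary["stages"]["screen"] = {
            "genes_in": len(results),
            "genes_selected": len(selected),
        }
    except Exception as exc:
        raise StageError("screen", str(exc)) from exc
    _write_summary(outdir, summary)

    # --- integrate --------------------------------------------------------
    try:
        expr = read_matrix(paths["expr"], kind="expression")
        records = integration.build_candidate_records(selected, meth, expr, annot)
        retained = integration.correlation_filter(records)
        integration.candidates_to_frame(records).sort_values(
            "score", ascending=False).to_csv(
            outdir / "candidates.tsv", sep="\t", index=False, lineterminator="\n")
        summary["stages"]["integrate"] = {
            "genes_in": len(records),
            "genes_passing_correlation": len(retained),
        }
    except Exception as exc:
        raise StageError("integrate", str(exc)) from exc
    _write_summary(outdir, summary)

    # --- evaluate ---------------------------------------------------------
    try:
        eval_cfg = dict(config.get("evaluate", {}))
        curve_points = eval_cfg.get("curve_points")
        curve = (diagnostics.fit_standard_curve(curve_points)
                 if curve_points else simulate.DEFAULT_CURVE)
        tissue = diagnostics.quantify_qmsp(read_qmsp(paths["qmsp_tissue"]), curve)
        saliva = diagnostics.quantify_qmsp(read_qmsp(paths["qmsp_saliva"]), curve)
        v_annot = read_annotation(paths.get("validation_annot", paths["annot"]))
        report = evaluate_assay(tissue, saliva, v_annot, eval_cfg.get("genes"))
        report["seed"] = seed
        report["config_hash"] = summary["config_hash"]
        (outdir / "evaluation.json").write_text(
            json.dumps(report, indent=2, default=float) + "\n")
        summary["stages"]["evaluate"] = {
            "genes": report["genes"],
            "panel_sensitivity_percent":
                report["saliva"]["panel"]["sensitivity_percent"],
            "panel_specificity_percent":
                report["saliva"]["panel"]["specificity_percent"],
        }
    except Exception as exc:
        raise StageError("evaluate", str(exc)) from exc

    summary["funnel"] = [
        summary["stages"]["screen"]["genes_in"],
        summary["stages"]["screen"]["genes_selected"],
        summary["stages"]["integrate"]["genes_passing_correlation"],
    ]
    _write_summary(outdir, summary)
    return summary


def _write_summary(outdir: Path, summary: dict[str, Any]) -> None:
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, default=str) + "\n"
    )
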