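"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

Discovery cohorts: normals with low, tight beta distributions; a heterogeneous
subset of tumors hypermethylated in the signal genes; expression negatively
coupled to methylation. Validation assays: paired tissue/saliva QMSP tables
with conditional saliva positivity and signal-free controls.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import (
    ExpressionMatrix,
    MethylationMatrix,
    QmspTable,
    SampleAnnotation,
    write_annotation,
    write_matrix,
    write_qmsp,
)
from .diagnostics import StandardCurve

# Ct values for synthetic positives are back-computed through this curve so
# that fit_standard_curve / quantify round-trips exactly.
DEFAULT_CURVE = StandardCurve(slope=-3.3, intercept=36.5, r_squared=1.0,
                              points=[(1.0, 33.2), (2.0, 29.9), (3.0, 26.6)])


@dataclass
class CohortSpec:
    n_tumor: int = 44
    n_normal: int = 25
    n_genes: int = 500
    n_signal_genes: int = 25
    outlier_fraction: float = 0.3
    effect_delta: float = 0.3
    normal_beta_mean: float = 0.03
    normal_beta_sd: float = 0.02
    expr_coupling_slope: float = -5.0
    expr_noise_sd: float = 1.0
    hpv_pos_fraction: float = 0.3
    hpv_effect_ratio: float = 0.5
    beta_noise: str = "gaussian"  # or "beta"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal_genes > self.n_genes:
            raise ValueError("n_signal_genes cannot exceed n_genes")
        for name in ("outlier_fraction", "effect_delta", "hpv_pos_fraction",
                     "hpv_effect_ratio"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.beta_noise not in ("gaussian", "beta"):
            raise ValueError("beta_noise must be 'gaussian' or 'beta'")


@dataclass
class PairedAssaySpec:
    n_cases: int = 59
    n_controls: int = 35
    tissue_positive_rate: dict[str, float] = field(
        default_factory=lambda: {"G1": 0.441, "G2": 0.39, "G3": 0.322}
    )
    saliva_sensitivity_given_tissue: dict[str, float] = field(
        default_factory=lambda: {"G1": 0.19, "G2": 0.43, "G3": 0.42}
    )
    level_scale: float = 5.0
    # Patient-level latent-factor (Gaussian copula) correlation between gene
    # events: co-methylated marker genes are positively dependent, which pulls
    # the any-marker panel rate below the independence value while leaving
    # per-gene marginal rates untouched.
    tissue_correlation: float = 0.6
    saliva_correlation: float = 0.9
    seed: int = 0

    # Controls carry no methylation signal: the saliva false-positive rate in
    # controls is fixed at zero, which forces 100% specificity.
    saliva_false_rate_controls: float = 0.0

    def __post_init__(self) -> None:
        if self.saliva_false_rate_controls != 0.0:
            raise ValueError("controls must carry zero signal")
        for name in ("tissue_correlation", "saliva_correlation"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        for d in (self.tissue_positive_rate, self.saliva_sensitivity_given_tissue):
            for g, r in d.items():
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"rate for {g} must be in [0, 1]")
        if set(self.tissue_positive_rate) != set(self.saliva_sensitivity_given_tissue):
            raise ValueError("gene sets of the two rate maps must match")
        if self.level_scale <= 0:
            raise ValueError("level_scale must be positive")


def _draw_normal_betas(rng: np.random.Generator, spec: CohortSpec, size) -> np.ndarray:
    if spec.beta_noise == "gaussian":
        return np.clip(rng.normal(spec.normal_beta_mean, spec.normal_beta_sd, size), 0.0, 1.0)
    # moment-matched Beta alternative
    m, s2 = spec.normal_beta_mean, spec.normal_beta_sd**2
    nu = m * (1 - m) / s2 - 1
    return rng.beta(m * nu, (1 - m) * nu, size)


def generate_discovery_cohort(
    spec: CohortSpec,
) -> tuple[MethylationMatrix, ExpressionMatrix, SampleAnnotation, pd.DataFrame]:
    """Generate (methylation, expression, annotation, truth) for a discovery run.

    Truth table: one row per signal gene with the comma-joined set of planted
    outlier tumor sample ids. Same seed => bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    tumor_ids = [f"T{i+1:03d}" for i in range(spec.n_tumor)]
    normal_ids = [f"N{i+1:03d}" for i in range(spec.n_normal)]
    samples = tumor_ids + normal_ids
    genes = [f"gene{i+1:04d}" for i in range(spec.n_genes)]
    signal_genes = genes[: spec.n_signal_genes]

    hpv_pos = rng.random(spec.n_tumor) < spec.hpv_pos_fraction

    beta = _draw_normal_betas(rng, spec, (spec.n_genes, len(samples)))
    truth_rows = []
    for gi, gene in enumerate(signal_genes):
        outlier_mask = rng.random(spec.n_tumor) < spec.outlier_fraction
        shift = np.where(hpv_pos, spec.effect_delta * spec.hpv_effect_ratio,
                         spec.effect_delta)
        beta[gi, : spec.n_tumor] = np.where(
            outlier_mask,
            np.clip(beta[gi, : spec.n_tumor] + shift, 0.0, 1.0),
            beta[gi, : spec.n_tumor],
        )
        truth_rows.append(
            {
                "gene": gene,
                "outlier_samples": ",".join(
                    tid for tid, f in zip(tumor_ids, outlier_mask) if f
                ),
            }
        )

    expr = 10.0 + spec.expr_coupling_slope * beta + rng.normal(
        0.0, spec.expr_noise_sd, beta.shape
    )

    meth = MethylationMatrix(pd.DataFrame(beta, index=genes, columns=samples), level="gene")
    expression = ExpressionMatrix(pd.DataFrame(expr, index=genes, columns=samples))
    annot = SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": samples,
                "patient_id": samples,
                "group": ["tumor"] * spec.n_tumor + ["normal"] * spec.n_normal,
                "specimen": ["tissue"] * len(samples),
                "hpv_copy_number": list(np.where(hpv_pos, 10.0, 0.0)) + [0.0] * spec.n_normal,
            }
        )
    )
    truth = pd.DataFrame(truth_rows)
    return meth, expression, annot, truth


def _level_to_ct(level: float, actin_q: float, curve: StandardCurve) -> float:
    """Back-compute a target Ct whose quantified ratio reproduces `level`."""
    q_target = level * actin_q / 100.0
    return curve.slope * np.log10(q_target) + curve.intercept


def generate_validation_assay(
    spec: PairedAssaySpec, curve: StandardCurve = DEFAULT_CURVE
) -> tuple[QmspTable, QmspTable, SampleAnnotation]:
    """Generate paired tissue/saliva QMSP tables plus annotation.

    Per case and gene, tissue is positive at the specified rate; saliva is
    positive only conditionally on tissue positivity. Controls are always
    negative (undetermined target Ct). Positive relative levels are log-normal
    scaled by level_scale, encoded as Ct values through the standard curve.
    """
    rng = np.random.default_rng(spec.seed)
    genes = sorted(spec.tissue_positive_rate)
    case_ids = [f"P{i+1:03d}" for i in range(spec.n_cases)]
    ctrl_ids = [f"C{i+1:03d}" for i in range(spec.n_controls)]
    actin_q = 100.0  # fixed well-amplified loading control

    # exchangeable Gaussian copula: per-patient latent + per-gene noise
    from scipy.stats import norm

    rt, rs = spec.tissue_correlation, spec.saliva_correlation
    z_t = rng.normal(size=spec.n_cases)
    z_s = rng.normal(size=spec.n_cases)
    u_tissue = norm.cdf(
        np.sqrt(rt) * z_t[:, None]
        + np.sqrt(1 - rt) * rng.normal(size=(spec.n_cases, len(genes)))
    )
    u_saliva = norm.cdf(
        np.sqrt(rs) * z_s[:, None]
        + np.sqrt(1 - rs) * rng.normal(size=(spec.n_cases, len(genes)))
    )

    rows_tissue, rows_saliva = [], []
    for pi, pid in enumerate(case_ids):
        for gi, gene in enumerate(genes):
            tissue_pos = u_tissue[pi, gi] < spec.tissue_positive_rate[gene]
            saliva_pos = tissue_pos and (
                u_saliva[pi, gi] < spec.saliva_sensitivity_given_tissue[gene]
            )
            for rows, positive, suffix in (
                (rows_tissue, tissue_pos, "t"),
                (rows_saliva, saliva_pos, "s"),
            ):
                if positive:
                    level = spec.level_scale * rng.lognormal(0.0, 1.0)
                    ct = _level_to_ct(level, actin_q, curve)
                    ct = min(ct, 37.9)  # keep synthetic positives detectable
                else:
                    ct = np.nan
                rows.append(
                    {
                        "sample_id": f"{pid}{suffix}",
                        "gene": gene,
                        "ct_target": ct,
                        "ct_actin": curve.slope * np.log10(actin_q) + curve.intercept,
                    }
                )
    for cid in ctrl_ids:
        for gene in genes:
            rows_saliva.append(
                {
                    "sample_id": f"{cid}s",
                    "gene": gene,
                    "ct_target": np.nan,
                    "ct_actin": curve.slope * np.log10(actin_q) + curve.intercept,
                }
            )

    annot_rows = []
    for pid in case_ids:
        annot_rows.append({"sample_id": f"{pid}t", "patient_id": pid,
                           "group": "tumor", "specimen": "tissue"})
        annot_rows.append({"sample_id": f"{pid}s", "patient_id": pid,
                           "group": "tumor", "specimen": "saliva"})
    for cid in ctrl_ids:
        annot_rows.append({"sample_id": f"{cid}s", "patient_id": cid,
                           "group": "normal", "specimen": "saliva"})
    annotation = SampleAnnotation(pd.DataFrame(annot_rows))
    return (
        QmspTable(pd.DataFrame(rows_tissue)),
        QmspTable(pd.DataFrame(rows_saliva)),
        annotation,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_bundle(
    outdir: str | Path,
    cohort_spec: Optional[CohortSpec] = None,
    assay_spec: Optional[PairedAssaySpec] = None,
) -> dict[str, str]:
    """Write a complete synthetic bundle (matrices, annotations, QMSP tables,
    truth table, config, MANIFEST with checksums). Returns file -> sha256."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort_spec = cohort_spec or CohortSpec()
    assay_spec = assay_spec or PairedAssaySpec(seed=cohort_spec.seed)

    meth, expr, annot, truth = generate_discovery_cohort(cohort_spec)
    tissue, saliva, v_annot = generate_validation_assay(assay_spec)

    write_matrix(meth, outdir / "methylation.tsv")
    write_matrix(expr, outdir / "expression.tsv")
    write_annotation(annot, outdir / "annotation.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False, lineterminator="\n")
    write_qmsp(tissue, outdir / "qmsp_tissue.tsv")
    write_qmsp(saliva, outdir / "qmsp_saliva.tsv")
    write_annotation(v_annot, outdir / "validation_annotation.tsv")
    config = {"cohort_spec": asdict(cohort_spec), "assay_spec": asdict(assay_spec)}
    (outdir / "config.json").write_text(json.dumps(config, indent=2) + "\n")

    files = sorted(p.name for p in outdir.iterdir() if p.name != "MANIFEST.json")
    manifest = {name: _sha256(outdir / name) for name in files}
    (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
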