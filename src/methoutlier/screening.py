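"""Rank-sum outlier screening of tumor vs normal beta values.

Per gene, a baseline cutoff is derived from the normal samples (Tukey fence
with a minimum-change floor), tumor samples beyond the cutoff are flagged as
outliers, and the gene is scored by the normalized sum of the flagged samples'
joint ranks. Genes are ranked by descending score; selection is by score
cutoff or top-k (ties included). An optional permutation null yields a
per-gene empirical p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import MethylationMatrix, SampleAnnotation, ValidationError

logger = logging.getLogger(__name__)

TAILS = ("right", "left", "both")


@dataclass
class OutlierConfig:
    """Screening parameters.

    delta_min is the minimum beta change regarded as biologically meaningful:
    the cutoff is floored at median(normals) +/- delta_min, so every called
    outlier differs from a typical normal by at least delta_min.
    """

    delta_min: float = 0.10
    fence_k: float = 1.5
    tail: str = "both"
    score_cutoff: Optional[float] = None
    top_k: Optional[int] = None
    n_permutations: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta_min <= 1.0:
            raise ValueError("delta_min must be in [0, 1]")
        if self.fence_k < 0:
            raise ValueError("fence_k must be nonnegative")
        if self.tail not in TAILS:
            raise ValueError(f"tail must be one of {TAILS}")
        if self.score_cutoff is not None and self.top_k is not None:
            raise ValueError("use exactly one of score_cutoff / top_k for selection")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")


@dataclass
class OutlierResult:
    gene_id: str
    tail: str
    baseline_cutoff: float
    outlier_samples: frozenset[str]
    score: float
    permutation_p: Optional[float] = None


def compute_beta(unmeth: float, meth: float) -> float:
    """beta = M / (U + M); NaN when U + M == 0."""
    if unmeth < 0 or meth < 0:
        raise ValueError("intensities must be nonnegative")
    total = unmeth + meth
    if total == 0:
        return float("nan")
    return meth / total


def compute_beta_matrix(
    unmeth: pd.DataFrame, meth: pd.DataFrame, level: str = "probe"
) -> MethylationMatrix:
    """Vectorized beta estimation from paired U/M intensity matrices."""
    if not unmeth.index.equals(meth.index) or not unmeth.columns.equals(meth.columns):
        raise ValidationError("U and M matrices must share rows and columns")
    u = unmeth.to_numpy(dtype=float)
    m = meth.to_numpy(dtype=float)
    if np.nanmin(u) < 0 or np.nanmin(m) < 0:
        raise ValueError("intensities must be nonnegative")
    total = u + m
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, m / total, np.nan)
    return MethylationMatrix(
        pd.DataFrame(beta, index=unmeth.index, columns=unmeth.columns), level=level
    )


def aggregate_probes(probe_matrix: MethylationMatrix, probe_map) -> MethylationMatrix:
    """Collapse probe-level betas to gene level by the per-sample maximum over
    a gene's probes; missing only where all probes are missing."""
    if probe_matrix.level != "probe":
        raise ValidationError("aggregate_probes expects a probe-level matrix")
    genes = [probe_map.gene_for(p) for p in probe_matrix.row_ids]
    grouped = probe_matrix.values.groupby(pd.Index(genes, name="gene_id")).max()
    return MethylationMatrix(grouped, level="gene")


def baseline_cutoff(
    normal_values: Sequence[float], config: OutlierConfig, tail: str
) -> float:
    """Normal-derived beta threshold: Tukey fence floored at median +/- delta_min."""
    vals = np.asarray(normal_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 3:
        raise ValidationError("need >= 3 non-missing normal values for a baseline")
    q25, med, q75 = np.quantile(vals, [0.25, 0.5, 0.75])  # type-7 interpolation
    iqr = q75 - q25
    if tail == "right":
        return max(q75 + config.fence_k * iqr, med + config.delta_min)
    if tail == "left":
        return min(q25 - config.fence_k * iqr, med - config.delta_min)
    raise ValueError("tail must be 'right' or 'left' for a single cutoff")


def call_outliers(
    tumor_values: pd.Series, cutoff: float, tail: str
) -> frozenset[str]:
    """Flag tumor samples strictly beyond the cutoff; missing never flagged."""
    if tail == "right":
        mask = tumor_values > cutoff
    elif tail == "left":
        mask = tumor_values < cutoff
    else:
        raise ValueError("tail must be 'right' or 'left'")
    return frozenset(tumor_values.index[mask.fillna(False)])


def rank_sum_score(
    values: pd.Series, flagged: Iterable[str], tail: str = "right"
) -> float:
    """S = sum over flagged samples of rank/N, ranks joint over all non-missing
    samples with midranks for ties. Left tail uses ranks of negated values so
    extreme-low outliers score high symmetrically."""
    obs = values.dropna()
    n = len(obs)
    flagged = set(flagged)
    if n == 0 or not flagged:
        return 0.0
    data = -obs.to_numpy() if tail == "left" else obs.to_numpy()
    ranks = pd.Series(rankdata(data), index=obs.index)
    return float(ranks.loc[sorted(flagged)].sum() / n)


def _score_one_tail(
    values: pd.Series,
    tumor_ids: Sequence[str],
    normal_ids: Sequence[str],
    config: OutlierConfig,
    tail: str,
) -> tuple[float, float, frozenset[str]]:
    cutoff = baseline_cutoff(values.loc[list(normal_ids)].to_numpy(), config, tail)
    flagged = call_outliers(values.loc[list(tumor_ids)], cutoff, tail)
    score = rank_sum_score(values, flagged, tail)
    return cutoff, score, flagged


def score_gene(
    values: pd.Series,
    tumor_ids: Sequence[str],
    normal_ids: Sequence[str],
    config: OutlierConfig,
) -> OutlierResult:
    """Score a single gene; with tail='both' keep the better-scoring tail."""
    tails = ("right", "left") if config.tail == "both" else (config.tail,)
    best: Optional[OutlierResult] = None
    for tail in tails:
        cutoff, score, flagged = _score_one_tail(
            values, tumor_ids, normal_ids, config, tail
        )
        res = OutlierResult(str(values.name), tail, cutoff, flagged, score)
        if best is None or res.score > best.score:
            best = res
    assert best is not None
    return best


def permutation_null(
    values: pd.Series,
    tumor_ids: Sequence[str],
    normal_ids: Sequence[str],
    config: OutlierConfig,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Empirical p for a gene's observed score under label permutation.

    Each permutation reassigns tumor/normal labels, re-derives the baseline
    cutoff from the permuted normals, and re-scores. Add-one estimator:
    p = (1 + #{S_perm >= S_obs}) / (1 + B).
    """
    if config.n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    observed = score_gene(values, tumor_ids, normal_ids, config).score
    all_ids = np.asarray(list(tumor_ids) + list(normal_ids))
    n_tumor = len(tumor_ids)
    exceed = 0
    for _ in range(config.n_permutations):
        perm = rng.permutation(all_ids)
        s = score_gene(values, perm[:n_tumor], perm[n_tumor:], config).score
        if s >= observed:
            exceed += 1
    return (1 + exceed) / (1 + config.n_permutations)


def screen_genes(
    meth: MethylationMatrix,
    annotation: SampleAnnotation,
    config: OutlierConfig,
) -> list[OutlierResult]:
    """Score every gene and return results sorted by descending score.

    Ordering within equal scores is by gene id for determinism.
    """
    if meth.level != "gene":
        raise ValidationError("screen_genes expects a gene-level matrix")
    tumor_ids = [s for s in annotation.samples_in_group("tumor") if s in meth.values.columns]
    normal_ids = [s for s in annotation.samples_in_group("normal") if s in meth.values.columns]
    if not tumor_ids or not normal_ids:
        raise ValidationError("both tumor and normal groups must be present")
    rng = np.random.default_rng(config.seed)
    results = []
    for gene_id, row in meth.values.iterrows():
        res = score_gene(row, tumor_ids, normal_ids, config)
        if config.n_permutations > 0:
            res.permutation_p = permutation_null(
                row, tumor_ids, normal_ids, config, rng=rng
            )
        results.append(res)
    results.sort(key=lambda r: (-r.score, r.gene_id))
    return results


def select_candidates(
    results: Sequence[OutlierResult], config: OutlierConfig
) -> list[OutlierResult]:
    """Select by score cutoff (score >= cutoff) or top-k with ties included."""
    ranked = sorted(results, key=lambda r: (-r.score, r.gene_id))
    if config.score_cutoff is not None:
        return [r for r in ranked if r.score >= config.score_cutoff]
    if config.top_k is not None:
        if config.top_k <= 0:
            return []
        if len(ranked) <= config.top_k:
            return list(ranked)
        kth = ranked[config.top_k - 1].score
        return [r for r in ranked if r.score >= kth]
    return list(ranked)


def results_to_frame(results: Sequence[OutlierResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene_id for r in results],
            "tail": [r.tail for r in results],
            "score": [r.score for r in results],
            "cutoff": [r.baseline_cutoff for r in results],
            "n_outliers": [len(r.outlier_samples) for r in results],
            "outlier_sample_ids": [
                ",".join(sorted(r.outlier_samples)) for r in results
            ],
            "permutation_p": [r.permutation_p for r in results],
        }
    )
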