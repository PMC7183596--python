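"""CASP-style evaluation of a weight vector on labelled decoy pools.

Per target: Pearson correlation between −E and the quality label, the quality
of the top-ranked model, the best quality among the first five ranked models,
and standardized (Z-score) versions of both selections. Reported aggregates
are per-target means and Z-score sums, mirroring the usual benchmark tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .scoring import TargetPool, WeightVector, combine, rank_pool

__all__ = ["TargetEvaluation", "EvaluationReport", "pearson",
           "zscore_of_selection", "evaluate"]


def pearson(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson product-moment correlation; errors on constant input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 observations")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(a, b).statistic)


def zscore_of_selection(selected_quality: float,
                        pool_qualities: Sequence[float]) -> float:
    """Standardized quality of a selected model within its pool.

    Uses the population standard deviation; a zero-variance pool yields 0
    with a warning.
    """
    q = np.asarray(pool_qualities, dtype=float)
    if len(q) < 2:
        raise ValueError("pool needs at least 2 models")
    sd = q.std()  # population sd
    if sd == 0:
        warnings.warn("zero-variance pool; Z-score set to 0")
        return 0.0
    return float((selected_quality - q.mean()) / sd)


@dataclass
class TargetEvaluation:
    target_id: str
    pearson_gdt: Optional[float]
    pearson_tm: Optional[float]
    top1_quality: float
    best_of_top5_quality: float
    z_top1: float
    z_best5: float
    top1_tm: Optional[float] = None
    best_of_top5_tm: Optional[float] = None


@dataclass
class EvaluationReport:
    per_target: dict[str, TargetEvaluation] = field(default_factory=dict)
    mean_pearson_gdt: float = float("nan")
    mean_pearson_tm: float = float("nan")
    mean_top1_quality: float = float("nan")
    mean_best_of_top5_quality: float = float("nan")
    z_sum_top1: float = float("nan")
    z_sum_best5: float = float("nan")
    n_skipped_correlations: int = 0


def evaluate(pools: Sequence[TargetPool], w: WeightVector,
             k: int = 5) -> EvaluationReport:
    """Score, rank, and evaluate every labelled pool with the given weights.

    Pools without GDT-TS labels are skipped with a warning; targets whose
    correlation is undefined (constant score or quality) are excluded from
    the correlation average but still contribute selection metrics.
    """
    report = EvaluationReport()
    for pool in pools:
        labelled = pool.labelled()
        if len(labelled) < 2:
            warnings.warn(f"pool {pool.target_id!r} lacks quality labels; skipped")
            continue
        ranked = rank_pool(labelled, w)
        qualities = np.array([m.gdt_ts for m in labelled.models])
        scores = np.array([combine(m.features, w) for m in labelled.models])

        try:
            r_gdt = pearson(-scores, qualities)
        except ValueError:
            r_gdt = None
            report.n_skipped_correlations += 1

        tms = [m.tm_score for m in labelled.models]
        r_tm = None
        if all(t is not None for t in tms):
            try:
                r_tm = pearson(-scores, tms)
            except ValueError:
                r_tm = None

        top_k = ranked[:k]
        top1_q = ranked[0].gdt_ts
        best5_q = max(m.gdt_ts for m in top_k)
        entry = TargetEvaluation(
            target_id=pool.target_id,
            pearson_gdt=r_gdt,
            pearson_tm=r_tm,
            top1_quality=top1_q,
            best_of_top5_quality=best5_q,
            z_top1=zscore_of_selection(top1_q, qualities),
            z_best5=zscore_of_selection(best5_q, qualities),
        )
        if all(t is not None for t in tms):
            entry.top1_tm = ranked[0].tm_score
            entry.best_of_top5_tm = max(m.tm_score for m in top_k)
        report.per_target[pool.target_id] = entry

    if not report.per_target:
        raise ValueError("no labelled pool to evaluate")

    entries = list(report.per_target.values())
    corrs = [e.pearson_gdt for e in entries if e.pearson_gdt is not None]
    if corrs:
        report.mean_pearson_gdt = float(np.mean(corrs))
    tm_corrs = [e.pearson_tm for e in entries if e.pearson_tm is not None]
    if tm_corrs:
        report.mean_pearson_tm = float(np.mean(tm_corrs))
    report.mean_top1_quality = float(np.mean([e.top1_quality for e in entries]))
    report.mean_best_of_top5_quality = float(
        np.mean([e.best_of_top5_quality for e in entries]))
    report.z_sum_top1 = float(np.sum([e.z_top1 for e in entries]))
    report.z_sum_best5 = float(np.sum([e.z_best5 for e in entries]))
    return report
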