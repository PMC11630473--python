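"""Prophage activity: phage-to-host ratio, classes, and group comparison.

After induction, the coverage of a replicating prophage exceeds that of
its host chromosome.  The phage-to-host ratio (PtoH) — mean coverage of
the prophage region divided by the median coverage of its genomic
neighborhood — is a proxy for phage genome copies per host chromosome.
Prophages are classed high-active (mean >= median + 3 corrected SD),
low-active (>= median + 1 SD) or inactive.  Plasmid-borne prophages get
a copy-number correction so that multi-copy replicons do not masquerade
as induction.  Group comparisons use Shapiro-Wilk normality checks
followed by the Wilcoxon rank-sum (Mann-Whitney U) test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .detection import BackgroundStats

logger = logging.getLogger(__name__)


@dataclass
class ActivityCall:
    prophage_id: str
    mean_coverage: float
    neighborhood_median: float
    neighborhood_corrected_std: float
    ptoh: float
    ptoh_corrected: float
    category: str  # high_active | low_active | inactive
    plasmid_copy_number: Optional[float] = None


def compute_ptoh(region_depths: np.ndarray, stats: BackgroundStats) -> float:
    """Mean region coverage over median neighborhood coverage."""
    if stats.median <= 0:
        raise ValueError("neighborhood median is 0; PtoH undefined")
    return float(np.mean(region_depths)) / stats.median


def correct_plasmid_ptoh(
    region_mean: float, genome_median: float, plasmid_copy_number: float
) -> tuple[float, float]:
    """PtoH for plasmid-borne prophages, corrected for replicon copy number.

    The raw ratio compares the region against the whole-genome median; the
    correction divides by the plasmid copy number measured from non-induced
    data, and only applies when the plasmid is multi-copy — the corrected
    value can only decrease.
    """
    if genome_median <= 0:
        raise ValueError("genome median is 0; PtoH undefined")
    if plasmid_copy_number < 1:
        logger.warning("copy number %.3f < 1 clamped to 1", plasmid_copy_number)
        plasmid_copy_number = 1.0
    raw = region_mean / genome_median
    corrected = raw / plasmid_copy_number if plasmid_copy_number > 1 else raw
    return raw, corrected


def classify_activity(mean_coverage: float, stats: BackgroundStats) -> str:
    """Activity class from the neighborhood background (inclusive thresholds)."""
    med, sd = stats.median, stats.corrected_std
    if sd == 0:
        if mean_coverage > med:
            logger.info("corrected std 0: mean above median classed high_active")
            return "high_active"
        return "inactive"
    if mean_coverage >= med + 3.0 * sd:
        return "high_active"
    if mean_coverage >= med + 1.0 * sd:
        return "low_active"
    return "inactive"


def call_activity(
    prophage_id: str,
    region_depths: np.ndarray,
    stats: BackgroundStats,
    genome_median: Optional[float] = None,
    plasmid_copy_number: Optional[float] = None,
) -> ActivityCall:
    """Full activity call for one prophage region."""
    mean_cov = float(np.mean(region_depths))
    ptoh = compute_ptoh(region_depths, stats)
    if plasmid_copy_number is not None:
        gm = genome_median if genome_median is not None else stats.median
        ptoh, corrected = correct_plasmid_ptoh(mean_cov, gm, plasmid_copy_number)
    else:
        corrected = ptoh
    return ActivityCall(
        prophage_id=prophage_id,
        mean_coverage=mean_cov,
        neighborhood_median=stats.median,
        neighborhood_corrected_std=stats.corrected_std,
        ptoh=ptoh,
        ptoh_corrected=corrected,
        category=classify_activity(mean_cov, stats),
        plasmid_copy_number=plasmid_copy_number,
    )


@dataclass
class GroupComparison:
    shapiro_p_a: float
    shapiro_p_b: float
    normal_a: bool
    normal_b: bool
    statistic: float
    p_value: float
    method: str  # exact | asymptotic


def compare_groups(
    group_a: Sequence[float], group_b: Sequence[float], alpha: float = 0.05
) -> GroupComparison:
    """Shapiro-Wilk per group, then two-sided Wilcoxon rank-sum.

    The rank-sum p is exact when both groups have at most 25 observations
    and the pooled data has no ties; otherwise the tie-corrected normal
    approximation with continuity correction is used.  A fully degenerate
    comparison (all pooled values identical) has p = 1 by symmetry.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    sw_a = sps.shapiro(a)
    sw_b = sps.shapiro(b)

    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.all(pooled == pooled[0]):
        return GroupComparison(
            sw_a.pvalue, sw_b.pvalue, sw_a.pvalue > alpha, sw_b.pvalue > alpha,
            float(len(a) * len(b) / 2.0), 1.0, "degenerate",
        )
    if not has_ties and len(a) <= 25 and len(b) <= 25:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        method = "asymptotic"
    return GroupComparison(
        float(sw_a.pvalue), float(sw_b.pvalue),
        sw_a.pvalue > alpha, sw_b.pvalue > alpha,
        float(res.statistic), float(min(res.pvalue, 1.0)), method,
    )
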