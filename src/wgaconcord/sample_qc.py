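"""Per-sample filtering and QC statistics, plus the anomalous-sample exclusion rule.

The QC layer mirrors a standard exome sanity check: apply the calling filter
(depth >= 11, quality > 30), count heterozygous and homozygous-alternate calls,
compute the het/hom and transition/transversion (Ts/Tv) ratios, and the mean
on-target coverage.  Samples whose het/hom ratio exceeds a configurable
exclusion threshold (default 3.0) are flagged and dropped from all cross-method
comparisons downstream — anomalously high ratios indicate contamination, tumor
heterogeneity or calling pathology rather than a usable call set.

Ts/Tv is implemented as transitions over transversions; exome-wide values near
3 indicate plausible call sets, and values in that range are only obtainable
with this orientation of the ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import List, Sequence

from .formats_io import Callset, CoverageTrack, IntervalSet, ThresholdConfig
from .util import round_half_away

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampleQC:
    """QC summary row for one sample/assay."""

    sample_id: str
    assay: str
    n_het: int
    n_hom: int
    het_hom_ratio: float  # nan when n_hom == 0
    ts_tv_ratio: float  # nan when no transversions
    mean_target_coverage: float
    excluded: bool = False
    exclusion_reason: str = ""


def filter_calls(callset: Callset, cfg: ThresholdConfig) -> Callset:
    """Retain exactly the calls with depth >= min_call_depth and qual > min_call_qual."""
    kept = tuple(
        c for c in callset.calls
        if c.depth >= cfg.min_call_depth and c.qual > cfg.min_call_qual
    )
    logger.info("filter_calls(%s/%s): %d in, %d retained",
                callset.sample_id, callset.assay, len(callset), len(kept))
    return callset.with_calls(kept)


def het_hom_ratio(callset: Callset) -> float:
    """count(het) / count(hom_alt); nan (flagged in the log) when no hom_alt calls."""
    n_het = sum(1 for c in callset if c.genotype == "het")
    n_hom = sum(1 for c in callset if c.genotype == "hom_alt")
    if n_hom == 0:
        logger.warning("het_hom_ratio(%s/%s): no hom_alt calls, ratio undefined",
                       callset.sample_id, callset.assay)
        return math.nan
    return n_het / n_hom


def ts_tv_ratio(callset: Callset) -> float:
    """Transitions (A<->G, C<->T) over transversions; nan when no transversions."""
    n_ts = sum(1 for c in callset if c.is_transition)
    n_tv = len(callset) - n_ts
    if n_tv == 0:
        logger.warning("ts_tv_ratio(%s/%s): no transversions, ratio undefined",
                       callset.sample_id, callset.assay)
        return math.nan
    return n_ts / n_tv


def mean_target_coverage(track: CoverageTrack, targets: IntervalSet) -> float:
    """Sum of depths over all target positions divided by total target length."""
    length = targets.total_length()
    if length == 0:
        raise ValueError("mean_target_coverage: empty target set")
    return track.sum_over(targets) / length


def compute_sample_qc(callset: Callset, track: CoverageTrack,
                      targets: IntervalSet, cfg: ThresholdConfig) -> SampleQC:
    """Filter a callset and assemble its QC row (ratios rounded to 2 decimals)."""
    filtered = filter_calls(callset, cfg)
    n_het = sum(1 for c in filtered if c.genotype == "het")
    n_hom = len(filtered) - n_het
    return SampleQC(
        sample_id=callset.sample_id,
        assay=callset.assay,
        n_het=n_het,
        n_hom=n_hom,
        het_hom_ratio=round_half_away(het_hom_ratio(filtered), 2),
        ts_tv_ratio=round_half_away(ts_tv_ratio(filtered), 2),
        mean_target_coverage=round_half_away(mean_target_coverage(track, targets), 2),
    )


def flag_anomalous(qcs: Sequence[SampleQC], cfg: ThresholdConfig) -> List[SampleQC]:
    """Mark samples whose het/hom ratio exceeds the exclusion threshold.

    An undefined (nan) ratio is also excluded: a sample with no homozygous
    calls cannot be compared on equal terms.
    """
    out: List[SampleQC] = []
    for qc in qcs:
        if math.isnan(qc.het_hom_ratio):
            reason = "het/hom ratio undefined (no hom_alt calls)"
            logger.warning("excluding %s/%s: %s", qc.sample_id, qc.assay, reason)
            out.append(replace(qc, excluded=True, exclusion_reason=reason))
        elif qc.het_hom_ratio > cfg.het_hom_exclusion:
            reason = (f"het/hom ratio {qc.het_hom_ratio:.2f} > "
                      f"{cfg.het_hom_exclusion:.2f}")
            logger.warning("excluding %s/%s: %s", qc.sample_id, qc.assay, reason)
            out.append(replace(qc, excluded=True, exclusion_reason=reason))
        else:
            out.append(replace(qc, excluded=False, exclusion_reason=""))
    return out
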