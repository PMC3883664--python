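"""Rescue analysis: explain discordant calls with the other method's unfiltered evidence.

A variant found by only one method may have been missed by the other because
the position was poorly covered there (a coverage artifact, not a disagreement)
or because the other method genuinely saw no variant reads at adequate depth.
Each unique call is classified against the opposite method's unfiltered track:

* ``low_cov``      — other-method depth <= 9 ("coverage < 10");
* ``cov_gap``      — depth exactly 10 (passes neither strict inequality of the
                     calling and low-coverage rules; reported separately rather
                     than silently absorbed);
* ``supported``    — depth >= 11 and the unfiltered evidence set contains a
                     matching (chrom, pos, alt) record;
* ``unsupported``  — depth >= 11 with no matching evidence.

For WGA-unique calls, the unsupported fraction is the false-positive indicator:
adequately covered positions where the unamplified data saw nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List

from .formats_io import Callset, CoverageTrack, ThresholdConfig, VariantCall
from .util import round_half_away

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RescueSummary:
    """Four-way classification of one method's unique calls against the other method."""

    n_unique: int
    n_low_cov: int
    n_cov_gap: int
    n_supported: int
    n_unsupported: int

    def __post_init__(self) -> None:
        total = self.n_low_cov + self.n_cov_gap + self.n_supported + self.n_unsupported
        if total != self.n_unique:
            raise ValueError(f"rescue classes sum to {total}, expected {self.n_unique}")

    @property
    def pct_low_cov(self) -> float:
        """Percent of unique calls at other-method depth <= 9 (1-decimal rounding)."""
        if self.n_unique == 0:
            return float("nan")
        return round_half_away(100.0 * self.n_low_cov / self.n_unique, 1)

    @property
    def pct_unsupported(self) -> float:
        if self.n_unique == 0:
            return float("nan")
        return round_half_away(100.0 * self.n_unsupported / self.n_unique, 1)


def rescue(unique_calls: Iterable[VariantCall], other_cov: CoverageTrack,
           other_evidence: Callset, cfg: ThresholdConfig | None = None) -> RescueSummary:
    """Classify one method's unique calls by the other method's depth and evidence.

    ``other_evidence`` is the unfiltered call evidence of the opposite method: a
    matching key counts as presence regardless of its depth or quality there.
    A coverage track missing a whole contig present in the calls is a hard
    error (a truncated track must not read as zero coverage).
    """
    cfg = cfg or ThresholdConfig()
    calls = list(unique_calls)
    for call in calls:
        if not other_cov.has_chrom(call.chrom):
            raise ValueError(
                f"coverage track {other_cov.sample_id}/{other_cov.assay} has no "
                f"contig {call.chrom!r} required by call {call.chrom}:{call.pos}")
    evidence_keys = other_evidence.keys()
    n_low = n_gap = n_sup = n_unsup = 0
    for call in calls:
        depth = other_cov.depth(call.chrom, call.pos)
        if depth <= cfg.low_cov_threshold - 1:
            n_low += 1
        elif depth < cfg.min_call_depth:
            n_gap += 1
        elif call.key in evidence_keys:
            n_sup += 1
        else:
            n_unsup += 1
    return RescueSummary(n_unique=len(calls), n_low_cov=n_low, n_cov_gap=n_gap,
                         n_supported=n_sup, n_unsupported=n_unsup)


@dataclass(frozen=True)
class RescueInterpretation:
    """Descriptive reading of the two rescue summaries (no hypothesis test)."""

    pct_unamp_unique_low_cov_in_wga: float
    pct_wga_unique_low_cov_in_unamp: float
    false_positive_indicator: float  # unsupported fraction of WGA-unique calls, percent
    notes: Dict[str, str]


def interpret(summary_wga_unique: RescueSummary,
              summary_unamp_unique: RescueSummary) -> RescueInterpretation:
    """Label the unsupported-at-adequate-coverage fraction of WGA-unique calls.

    WGA-unique calls that the unamplified data covered well yet showed no
    variant reads for are the signature of amplification false positives;
    unamplified-unique calls at low WGA coverage are the signature of uneven
    WGA coverage, not of disagreement.
    """
    notes = {
        "false_positive_indicator": (
            "percent of WGA-unique calls with adequate unamplified coverage "
            "(depth >= 11) and no variant evidence in the unamplified data"),
        "low_cov": "percent of unique calls with other-method depth <= 9",
    }
    # no WGA-unique calls at all means no evidence of false positives
    indicator = (0.0 if summary_wga_unique.n_unique == 0
                 else summary_wga_unique.pct_unsupported)
    return RescueInterpretation(
        pct_unamp_unique_low_cov_in_wga=summary_unamp_unique.pct_low_cov,
        pct_wga_unique_low_cov_in_unamp=summary_wga_unique.pct_low_cov,
        false_positive_indicator=indicator,
        notes=notes,
    )
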