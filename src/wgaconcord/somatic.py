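"""Tumor-specific mutation identification by normal subtraction.

A tumor call is a somatic candidate when its (chrom, pos, alt) key is absent
from the matched WGA normal call set AND the normal data covered the position
adequately (depth >= 11).  The coverage gate is essential: a position the
normal data could not evaluate — including allelic dropout in the normal — must
be "unevaluable", never "somatic", otherwise amplification artifacts in the
normal manufacture mutations.

Downstream summaries quantify how many somatic candidates are confirmed by the
unamplified tumor data, and what fraction of each concordance class is somatic
(amplification false positives concentrate in the WGA-only class).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Tuple

from .concordance import ConcordancePartition
from .formats_io import Callset, CoverageTrack, ThresholdConfig, VariantCall, VariantKey
from .util import round_half_away

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SomaticCallset:
    """Tumor-specific candidate mutations for one patient (from the WGA tumor)."""

    patient_id: str
    calls: Tuple[VariantCall, ...]
    normal_depths: Dict[VariantKey, int]

    def __post_init__(self) -> None:
        for call in self.calls:
            if call.key not in self.normal_depths:
                raise ValueError(f"missing normal depth for {call.key}")

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    def keys(self) -> frozenset:
        return frozenset(c.key for c in self.calls)


def subtract_normal(tumor: Callset, normal: Callset, normal_cov: CoverageTrack,
                    cfg: ThresholdConfig | None = None) -> SomaticCallset:
    """Retain tumor calls absent from the normal at normal depth >= min_call_depth."""
    cfg = cfg or ThresholdConfig()
    if tumor.sample_id != normal.sample_id:
        raise ValueError(f"patient mismatch: {tumor.sample_id} vs {normal.sample_id}")
    normal_keys = normal.keys()
    kept = []
    depths: Dict[VariantKey, int] = {}
    n_in_normal = n_unevaluable = 0
    for call in tumor:
        if call.key in normal_keys:
            n_in_normal += 1
            continue
        nd = normal_cov.depth(call.chrom, call.pos)
        if nd < cfg.min_call_depth:
            n_unevaluable += 1
            continue
        kept.append(call)
        depths[call.key] = nd
    logger.info("subtract_normal(%s): %d tumor calls -> %d somatic "
                "(%d germline, %d unevaluable normal coverage)",
                tumor.sample_id, len(tumor), len(kept), n_in_normal, n_unevaluable)
    return SomaticCallset(patient_id=tumor.sample_id, calls=tuple(kept),
                          normal_depths=depths)


def confirm_in_unamplified(somatic: SomaticCallset, unamp_tumor: Callset) -> float:
    """Percent of somatic candidates with a key match in the unamplified tumor calls.

    The unamplified call set should already be filtered and restricted to the
    shared target space so that capture-design differences do not deflate the
    statistic.  Returns nan (flagged) for an empty somatic set.
    """
    if len(somatic) == 0:
        logger.warning("confirm_in_unamplified(%s): empty somatic set", somatic.patient_id)
        return math.nan
    unamp_keys = unamp_tumor.keys()
    n_confirmed = sum(1 for c in somatic if c.key in unamp_keys)
    return round_half_away(100.0 * n_confirmed / len(somatic), 1)


def mutation_fraction_by_class(p: ConcordancePartition,
                               somatic: SomaticCallset) -> Dict[str, float]:
    """Percent of each concordance class (wga_only/shared/unamp_only) that is somatic.

    Empty classes yield nan and are flagged so cohort averages can skip them.
    """
    if p.patient_id != somatic.patient_id:
        raise ValueError(f"patient mismatch: {p.patient_id} vs {somatic.patient_id}")
    somatic_keys = somatic.keys()
    out: Dict[str, float] = {}
    for cls, keys in (("wga_only", p.wga_only), ("shared", p.shared),
                      ("unamp_only", p.unamp_only)):
        if not keys:
            logger.warning("mutation_fraction_by_class(%s): class %s empty",
                           p.patient_id, cls)
            out[cls] = math.nan
            continue
        n_somatic = sum(1 for k in keys if k in somatic_keys)
        out[cls] = round_half_away(100.0 * n_somatic / len(keys), 1)
    return out
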