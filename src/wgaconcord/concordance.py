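"""Concordance of WGA vs unamplified tumor call sets in the shared capture space.

Both call sets are restricted to the coding regions covered by both capture
designs and decomposed on the (chrom, pos, alt) match key into three disjoint
classes: WGA-only, shared, unamplified-only.  Summaries include class counts
and percentages (two denominator conventions), per-class coverage five-number
summaries (low coverage of the unique classes is the main driver of
discordance), and the agreement of variant allele fractions between methods as
a squared Pearson correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import Callset, CoverageTrack, IntervalSet, VariantCall, VariantKey
from .util import pct

logger = logging.getLogger(__name__)

CLASSES = ("wga_only", "shared", "unamp_only")


@dataclass(frozen=True)
class ConcordancePartition:
    """The WGA-only / shared / unamplified-only decomposition of one patient's calls."""

    patient_id: str
    wga_only: Dict[VariantKey, VariantCall]
    shared: Dict[VariantKey, Tuple[VariantCall, VariantCall]]  # (wga, unamp)
    unamp_only: Dict[VariantKey, VariantCall]

    @property
    def counts(self) -> Tuple[int, int, int]:
        return (len(self.wga_only), len(self.shared), len(self.unamp_only))

    @property
    def n_union(self) -> int:
        return sum(self.counts)


def shared_target_space(design_a: IntervalSet, design_b: IntervalSet,
                        coding: IntervalSet) -> IntervalSet:
    """Coding regions covered by both capture designs (three-way intersection)."""
    space = coding.intersect(design_a).intersect(design_b, label="shared_target")
    if not space:
        logger.warning("shared_target_space: empty intersection")
    return space


def restrict(callset: Callset, space: IntervalSet) -> Callset:
    """Keep only calls whose position lies inside the interval set."""
    return callset.with_calls(c for c in callset if space.contains(c.chrom, c.pos))


def partition(wga: Callset, unamp: Callset, space: IntervalSet) -> ConcordancePartition:
    """Restrict both call sets to ``space`` and match them on (chrom, pos, alt)."""
    if wga.assay != "wga_tumor":
        raise ValueError(f"expected a wga_tumor callset, got {wga.assay}")
    if unamp.assay != "unamplified_tumor":
        raise ValueError(f"expected an unamplified_tumor callset, got {unamp.assay}")
    if wga.sample_id != unamp.sample_id:
        raise ValueError(f"patient mismatch: {wga.sample_id} vs {unamp.sample_id}")
    wga_keys = restrict(wga, space).by_key()
    unamp_keys = restrict(unamp, space).by_key()
    shared = {k: (wga_keys[k], unamp_keys[k]) for k in wga_keys.keys() & unamp_keys.keys()}
    wga_only = {k: v for k, v in wga_keys.items() if k not in shared}
    unamp_only = {k: v for k, v in unamp_keys.items() if k not in shared}
    return ConcordancePartition(patient_id=wga.sample_id, wga_only=wga_only,
                                shared=shared, unamp_only=unamp_only)


def partition_percentages(p: ConcordancePartition,
                          convention: str = "union") -> Tuple[float, float, float]:
    """Class percentages (wga_only, shared, unamp_only), whole-percent rounding.

    ``union``: every class over the union count.  ``method_specific``: each
    unique class over its own method's total (unique + shared), shared over the
    union — the convention of the per-patient summary rows.
    """
    n_wga_only, n_shared, n_unamp_only = p.counts
    union = p.n_union
    if union == 0:
        raise ValueError("partition_percentages: empty union")
    if convention == "union":
        return (pct(n_wga_only, union), pct(n_shared, union), pct(n_unamp_only, union))
    if convention == "method_specific":
        return (pct(n_wga_only, n_wga_only + n_shared),
                pct(n_shared, union),
                pct(n_unamp_only, n_unamp_only + n_shared))
    raise ValueError(f"unknown convention {convention!r}")


def wga_shared_fraction(p: ConcordancePartition) -> float:
    """Percent of WGA calls that are shared with the unamplified data: shared/(wga_only+shared)."""
    n_wga_only, n_shared, _ = p.counts
    if n_wga_only + n_shared == 0:
        raise ValueError("wga_shared_fraction: no WGA calls in partition")
    return pct(n_shared, n_wga_only + n_shared)


def coverage_by_class(p: ConcordancePartition, cov_wga: CoverageTrack,
                      cov_unamp: CoverageTrack) -> pd.DataFrame:
    """Five-number depth summaries per class and per track (boxplot-ready).

    Rows: (class, track, n, min, q1, median, q3, max); an empty class yields a
    flagged row with nan summaries.
    """
    rows: List[dict] = []
    members = {
        "wga_only": list(p.wga_only),
        "shared": list(p.shared),
        "unamp_only": list(p.unamp_only),
    }
    for cls, keys in members.items():
        sites = [(k[0], k[1]) for k in keys]
        for track_name, track in (("wga", cov_wga), ("unamp", cov_unamp)):
            if not sites:
                rows.append({"class": cls, "track": track_name, "n": 0,
                             "min": math.nan, "q1": math.nan, "median": math.nan,
                             "q3": math.nan, "max": math.nan, "empty": True})
                continue
            depths = track.depths_at(sites)
            q1, med, q3 = np.percentile(depths, [25, 50, 75])
            rows.append({"class": cls, "track": track_name, "n": len(depths),
                         "min": float(depths.min()), "q1": float(q1),
                         "median": float(med), "q3": float(q3),
                         "max": float(depths.max()), "empty": False})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class VafPair:
    """Variant allele fraction of one shared call in each method."""

    key: VariantKey
    vaf_wga: float
    vaf_unamp: float


@dataclass(frozen=True)
class VafRegression:
    r2: float
    slope: float
    intercept: float
    n: int


def vaf_pairs(p: ConcordancePartition) -> List[VafPair]:
    """Paired VAFs (alt_depth/depth per method) for every shared call."""
    return [VafPair(key=k, vaf_wga=w.vaf, vaf_unamp=u.vaf)
            for k, (w, u) in sorted(p.shared.items())]


def vaf_r2(pairs: List[VafPair]) -> VafRegression:
    """Squared Pearson correlation of the paired VAFs plus the least-squares line.

    Requires at least 3 pairs and nonzero variance on both axes; otherwise the
    statistic is undefined and returned as nan (flagged in the log).
    """
    if len(pairs) < 3:
        logger.warning("vaf_r2: fewer than 3 shared calls, undefined")
        return VafRegression(math.nan, math.nan, math.nan, len(pairs))
    x = np.array([q.vaf_wga for q in pairs])
    y = np.array([q.vaf_unamp for q in pairs])
    if np.var(x) == 0 or np.var(y) == 0:
        logger.warning("vaf_r2: zero variance in VAFs, undefined")
        return VafRegression(math.nan, math.nan, math.nan, len(pairs))
    fit = stats.linregress(x, y)
    return VafRegression(r2=fit.rvalue ** 2, slope=fit.slope,
                         intercept=fit.intercept, n=len(pairs))
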