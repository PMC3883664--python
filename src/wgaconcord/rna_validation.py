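"""RNA-seq-based validation of DNA variant calls.

Two complementary analyses:

1. Coverage check — what fraction of tumor-specific mutations fall at positions
   the RNA-seq alignment covers with depth <= 9?  Those cannot be validated by
   RNA (the gene is silent or too lowly expressed); the complement is the
   RNA-validatable fraction.

2. Bi-allelic expression — genes qualify as expressed when they rank in the top
   75% by FPKM and have FPKM >= 1; among expressed genes with FPKM above the
   transcript threshold (2.8), a gene is called bi-allelically expressed when it
   contains at least one heterozygous RNA call whose minor allele fraction
   min(VAF, 1-VAF) is >= 20%.  Only bi-allelic genes can validate heterozygous
   DNA variants, so the fraction of bi-allelic genes that contain a DNA variant
   seen by both DNA methods bounds what RNA-based validation can achieve.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from typing import Dict, List, Sequence, Set

from .formats_io import (Callset, CoverageTrack, ExpressionTable, GeneModel,
                         ThresholdConfig)
from .somatic import SomaticCallset
from .util import round_half_away

logger = logging.getLogger(__name__)


def rna_coverage_check(somatic: SomaticCallset, rna_cov: CoverageTrack,
                       cfg: ThresholdConfig | None = None) -> float:
    """Percent of somatic positions with RNA depth <= 9; nan for an empty somatic set."""
    cfg = cfg or ThresholdConfig()
    if len(somatic) == 0:
        logger.warning("rna_coverage_check(%s): empty somatic set", somatic.patient_id)
        return math.nan
    n_low = sum(
        1 for c in somatic
        if rna_cov.depth(c.chrom, c.pos) <= cfg.low_cov_threshold - 1
    )
    return round_half_away(100.0 * n_low / len(somatic), 1)


def expressed_genes(expr: ExpressionTable, cfg: ThresholdConfig | None = None) -> Set[str]:
    """Genes in the top expressed_quantile by FPKM that also have FPKM >= fpkm_min.

    Genes are ranked by FPKM descending; ranks up to ceil(quantile * N) are
    kept, then the FPKM floor is applied.  Ties at the rank boundary are broken
    by gene_id lexicographic order so the set is deterministic.
    """
    cfg = cfg or ThresholdConfig()
    if len(expr) == 0:
        return set()
    ranked = sorted(expr.items(), key=lambda kv: (-kv[1], kv[0]))
    cutoff = math.ceil(cfg.expressed_quantile * len(ranked))
    return {g for g, f in ranked[:cutoff] if f >= cfg.fpkm_min}


class GeneIndex:
    """Bisect index from genomic position to containing gene ids."""

    def __init__(self, genes: Sequence[GeneModel]):
        by_chrom: Dict[str, List[tuple]] = {}
        for gm in genes:
            for chrom, start, end in gm.intervals.intervals:
                by_chrom.setdefault(chrom, []).append((start, end, gm.gene_id))
        self._by_chrom = {}
        self._starts: Dict[str, List[int]] = {}
        self._prefix_max_end: Dict[str, List[int]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            self._by_chrom[chrom] = ivs
            self._starts[chrom] = [s for s, _, _ in ivs]
            # running max of interval ends lets the left-scan stop as soon as no
            # earlier interval can still reach pos (genes may overlap in
            # user-supplied models even though the simulator never emits them)
            run, prefix = 0, []
            for _, e, _ in ivs:
                run = max(run, e)
                prefix.append(run)
            self._prefix_max_end[chrom] = prefix

    def genes_at(self, chrom: str, pos: int) -> List[str]:
        """Gene ids whose intervals contain the 1-based position (s < pos <= e)."""
        ivs = self._by_chrom.get(chrom, [])
        if not ivs:
            return []
        i = bisect_right(self._starts[chrom], pos - 1) - 1
        prefix = self._prefix_max_end[chrom]
        hits = []
        while i >= 0 and prefix[i] >= pos:
            s, e, gid = ivs[i]
            if pos <= e:
                hits.append(gid)
            i -= 1
        return hits


def biallelic_genes(rna_calls: Callset, expressed: Set[str],
                    genes: Sequence[GeneModel], expr: ExpressionTable,
                    cfg: ThresholdConfig | None = None) -> Set[str]:
    """Expressed genes with FPKM > fpkm_transcript_min showing bi-allelic expression.

    A gene qualifies when it contains >= 1 heterozygous RNA call (the callset
    should already be depth/quality filtered) whose minor allele fraction
    min(VAF, 1-VAF) >= minor_allele_min.  RNA calls mapping to no gene are
    counted and logged, not an error.
    """
    cfg = cfg or ThresholdConfig()
    qualifying = {g for g in expressed if expr.fpkm(g) > cfg.fpkm_transcript_min}
    index = GeneIndex(genes)
    out: Set[str] = set()
    n_unmapped = 0
    for call in rna_calls:
        if call.genotype != "het":
            continue
        maf = min(call.vaf, 1.0 - call.vaf)
        if math.isnan(maf) or maf < cfg.minor_allele_min:
            continue
        hits = index.genes_at(call.chrom, call.pos)
        if not hits:
            n_unmapped += 1
            continue
        out.update(g for g in hits if g in qualifying)
    if n_unmapped:
        logger.info("biallelic_genes(%s): %d het RNA calls mapped to no gene",
                    rna_calls.sample_id, n_unmapped)
    return out


def biallelic_dna_support(biallelic: Set[str], wga: Callset, unamp: Callset,
                          genes: Sequence[GeneModel]) -> float:
    """Percent of bi-allelic genes containing >= 1 DNA variant key seen by both methods.

    The DNA call sets should be filtered and restricted to the shared target
    space.  Returns nan (flagged) when the bi-allelic set is empty.
    """
    if not biallelic:
        logger.warning("biallelic_dna_support: empty bi-allelic gene set")
        return math.nan
    shared_keys = wga.keys() & unamp.keys()
    index = GeneIndex(genes)
    supported: Set[str] = set()
    for chrom, pos, _alt in shared_keys:
        for gene_id in index.genes_at(chrom, pos):
            if gene_id in biallelic:
                supported.add(gene_id)
    return round_half_away(100.0 * len(supported) / len(biallelic), 1)
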