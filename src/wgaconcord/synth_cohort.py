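"""Synthetic multi-patient cohort generator with WGA-style amplification bias.

The generator emulates the statistical structure of a 16-patient NSCLC-like
tumor/normal exome comparison on a compressed toy genome: per-patient germline
variants with a realistic het/hom and transition/transversion composition,
tumor-specific somatic mutations, two overlapping capture designs, per-base
coverage that is strongly over-dispersed for the WGA assays (the mechanism that
drives discordance at coverage filtering), allelic dropout at heterozygous
sites in WGA assays, amplification false positives that survive the calling
filter, and RNA expression with silent / mono-allelic / bi-allelic genes.

Observed call sets are the truth passed through depth sampling, the calling
filter (depth >= 11, quality > 30), dropout, and false-positive injection.
Alongside the filtered VCFs the generator emits *unfiltered evidence* VCFs
(every site with at least one variant-supporting read, regardless of depth or
quality) — the stand-in for inspecting alignment files without a coverage
filter — plus per-base coverage TSVs, the capture/coding/gene BEDs and a
per-patient FPKM table.

Depth model: negative-binomial sampling parameterized by a mean and a
*dispersion* ``d`` with ``var = mu + d * mu^2`` (``d -> 0`` recovers Poisson).
WGA dispersion must be at least the unamplified dispersion.  Quality is an
increasing function of variant-supporting reads plus Gaussian noise, so that at
deep coverage real variants essentially never fail the quality filter.

Everything is driven by one seed: the same configuration and seed give
byte-identical output trees.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .formats_io import (ASSAYS, Callset, CoverageTrack, ExpressionTable,
                         GeneModel, IntervalSet, ThresholdConfig, VariantCall,
                         write_bed, write_coverage_tsv, write_expression_tsv,
                         write_gene_models, write_vcf)

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS_OF = {"A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G")}

# quality model: qual = QUAL_BASE + QUAL_PER_ALT_READ * alt_depth + N(0, QUAL_SD)
QUAL_BASE = 40.0
QUAL_PER_ALT_READ = 0.5
QUAL_SD = 5.0
HOM_ALT_VAF = 0.98  # residual reference reads from sequencing error

DNA_ASSAYS = ("wga_tumor", "wga_normal", "unamplified_tumor")
WGA_ASSAYS = ("wga_tumor", "wga_normal")
TUMOR_ASSAYS = ("wga_tumor", "unamplified_tumor", "rna_tumor")


@dataclass(frozen=True)
class CaptureParams:
    """Interval-generation parameters for one capture design.

    ``overlap_fraction`` is the fraction of gene loci shared between the two
    designs (taken from design A's params; the designs are built jointly).
    """

    n_intervals: int
    interval_length: int
    overlap_fraction: float

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_fraction <= 1):
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.n_intervals < 1 or self.interval_length < 1:
            raise ValueError("capture design needs >= 1 interval of length >= 1")


@dataclass(frozen=True)
class CohortConfig:
    """All simulator parameters in one auditable place.

    Defaults emulate the cohort conditions of the analysis this package
    implements: 16 patients, ~12k germline SNVs each with het fraction 0.65
    (het/hom ~ 1.9) and transition probability 0.75 (Ts/Tv ~ 3), two capture
    designs covering most of a 150 kb coding space on a 2 Mb toy genome, WGA
    coverage that is deeply over-dispersed relative to unamplified coverage,
    5% allelic dropout, and an amplification false-positive rate expressed per
    Mb of WGA target (the toy genome is compressed ~200x relative to a real
    exome, so the per-Mb rate is scaled up accordingly to yield realistic
    per-patient counts).
    """

    n_patients: int = 16
    genome: Tuple[Tuple[str, int], ...] = (("chr1", 1_000_000), ("chr2", 1_000_000))
    n_genes: int = 375
    gene_length: int = 400
    n_germline_sites: int = 12_000
    het_fraction: float = 0.65
    ts_prob: float = 0.75
    n_somatic: int = 1_500
    capture_a: CaptureParams = CaptureParams(360, 500, 0.90)
    capture_b: CaptureParams = CaptureParams(345, 500, 0.90)
    depth_mean_unamp: float = 74.0
    depth_mean_wga: float = 60.0
    wga_dispersion: float = 1.0
    unamp_dispersion: float = 0.3
    dropout_prob: float = 0.05
    wga_fp_rate: float = 8_000.0  # expected false variants per Mb of WGA target
    purity: float = 1.0  # fraction of tumor cells carrying somatic alleles
    n_rna_patients: int = 11
    rna_expressed_fraction: float = 0.40
    rna_monoallelic_fraction: float = 0.60
    fpkm_lognorm_mu: float = 1.3
    fpkm_lognorm_sigma: float = 1.2
    rna_depth_per_fpkm: float = 10.0
    rna_dispersion: float = 0.2
    seed: int = 2014

    def __post_init__(self) -> None:
        for name in ("het_fraction", "ts_prob", "dropout_prob", "purity",
                     "rna_expressed_fraction", "rna_monoallelic_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_mean_unamp <= 0 or self.depth_mean_wga <= 0:
            raise ValueError("depth means must be > 0")
        if self.wga_dispersion < self.unamp_dispersion:
            raise ValueError("wga_dispersion must be >= unamp_dispersion")
        if self.wga_fp_rate < 0:
            raise ValueError("wga_fp_rate must be >= 0")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")

    @classmethod
    def small(cls, **overrides) -> "CohortConfig":
        """A scaled-down configuration (same structure) for fast exercises."""
        base = dict(
            n_patients=2,
            genome=(("chr1", 120_000), ("chr2", 120_000)),
            n_genes=60,
            gene_length=300,
            n_germline_sites=800,
            n_somatic=120,
            capture_a=CaptureParams(56, 400, 0.90),
            capture_b=CaptureParams(54, 400, 0.90),
            wga_fp_rate=4_000.0,
            n_rna_patients=2,
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["genome"] = [list(g) for g in self.genome]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "genome" in d:
            d["genome"] = tuple((str(c), int(l)) for c, l in d["genome"])
        for key in ("capture_a", "capture_b"):
            if key in d and isinstance(d[key], Mapping):
                d[key] = CaptureParams(**d[key])
        return cls(**d)


@dataclass(frozen=True)
class TruthVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    zygosity: str  # "het" | "hom"

    @property
    def key(self) -> Tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)


@dataclass
class PatientTruth:
    """Ground truth for one simulated patient: the key for parameter-recovery tests."""

    patient_id: str
    germline: List[TruthVariant]
    somatic: List[TruthVariant]
    false_positives: Dict[str, List[Tuple[str, int, str]]]  # assay -> keys
    dropout_lost: Dict[str, List[Tuple[str, int, str]]]  # assay -> het keys lost
    dropout_to_hom: Dict[str, List[Tuple[str, int, str]]]  # assay -> het keys -> hom
    gene_class: Dict[str, str]  # gene_id -> silent | mono | bi
    fpkm: Dict[str, float]
    has_rna: bool


@dataclass
class TruthSet:
    patients: Dict[str, PatientTruth]


@dataclass
class PatientData:
    """Observed (simulated) data for one patient, in memory."""

    patient_id: str
    callsets: Dict[str, Callset]  # filtered calls per assay
    evidence: Dict[str, Callset]  # unfiltered variant evidence, DNA assays only
    coverage: Dict[str, CoverageTrack]
    expression: Optional[ExpressionTable]
    has_rna: bool


@dataclass
class SimulatedCohort:
    config: CohortConfig
    thresholds: ThresholdConfig
    truth: TruthSet
    genes: List[GeneModel]
    capture_a: IntervalSet
    capture_b: IntervalSet
    coding: IntervalSet
    patients: Dict[str, PatientData]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _negbin(rng: np.random.Generator, mean: float, dispersion: float,
            size: int) -> np.ndarray:
    """Over-dispersed depths with var = mean + dispersion * mean^2."""
    if size == 0:
        return np.zeros(0, dtype=np.int64)
    if dispersion <= 0:
        return rng.poisson(mean, size=size).astype(np.int64)
    k = 1.0 / dispersion
    p = k / (k + mean)
    return rng.negative_binomial(k, p, size=size).astype(np.int64)


def _alt_allele(rng: np.random.Generator, ref: str, ts_prob: float) -> str:
    if rng.random() < ts_prob:
        return _TRANSITION_OF[ref]
    return _TRANSVERSIONS_OF[ref][rng.integers(0, 2)]


class _DesignDepths:
    """Per-chromosome sorted (positions, depths) arrays for one assay's target."""

    def __init__(self, rng: np.random.Generator, target: IntervalSet,
                 mean: float, dispersion: float):
        self.arrays: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for chrom in target.chroms:
            pos = target.positions(chrom)
            depth = _negbin(rng, mean, dispersion, len(pos))
            self.arrays[chrom] = (pos, depth)

    def depth_at(self, chrom: str, pos: int) -> int:
        entry = self.arrays.get(chrom)
        if entry is None:
            return 0
        positions, depths = entry
        i = np.searchsorted(positions, pos)
        if i < len(positions) and positions[i] == pos:
            return int(depths[i])
        return 0

    def track(self, sample_id: str, assay: str) -> CoverageTrack:
        return CoverageTrack(sample_id, assay, self.arrays)


def _build_genes(cfg: CohortConfig) -> List[GeneModel]:
    """Evenly spaced, non-overlapping single-interval genes tiling the genome."""
    total_len = sum(l for _, l in cfg.genome)
    genes: List[GeneModel] = []
    gi = 0
    for chrom, length in cfg.genome:
        n_here = round(cfg.n_genes * length / total_len)
        if gi + n_here > cfg.n_genes or (chrom, length) == cfg.genome[-1]:
            n_here = cfg.n_genes - gi
        if n_here <= 0:
            continue
        spacing = length // n_here
        margin = max(cfg.capture_a.interval_length, cfg.capture_b.interval_length)
        if spacing <= cfg.gene_length + margin:
            raise ValueError(
                "target space too small: gene spacing "
                f"{spacing} <= gene_length + capture interval ({cfg.gene_length} + {margin})")
        for i in range(n_here):
            start = i * spacing + (spacing - cfg.gene_length) // 2
            gene_id = f"G{gi:04d}"
            genes.append(GeneModel(
                gene_id=gene_id,
                intervals=IntervalSet([(chrom, start, start + cfg.gene_length)],
                                      label=gene_id)))
            gi += 1
    return genes


def _build_captures(cfg: CohortConfig, genes: Sequence[GeneModel],
                    rng: np.random.Generator) -> Tuple[IntervalSet, IntervalSet]:
    """Two capture designs as padded intervals over (partially shared) gene loci."""
    n = len(genes)
    na = min(cfg.capture_a.n_intervals, n)
    nb = min(cfg.capture_b.n_intervals, n)
    m = round(cfg.capture_a.overlap_fraction * min(na, nb))
    loci_a = np.sort(rng.choice(n, size=na, replace=False))
    shared = np.sort(rng.choice(loci_a, size=m, replace=False))
    outside = np.setdiff1d(np.arange(n), loci_a)
    extra_b = (np.sort(rng.choice(outside, size=min(nb - m, len(outside)), replace=False))
               if nb - m > 0 else np.array([], dtype=int))
    loci_b = np.sort(np.concatenate([shared, extra_b]))

    def design(loci: np.ndarray, params: CaptureParams, label: str) -> IntervalSet:
        ivs = []
        for idx in loci:
            chrom, s, e = genes[int(idx)].intervals.intervals[0]
            center = (s + e) // 2
            start = max(0, center - params.interval_length // 2)
            ivs.append((chrom, start, start + params.interval_length))
        return IntervalSet(ivs, label=label)

    return (design(loci_a, cfg.capture_a, "capture_a"),
            design(loci_b, cfg.capture_b, "capture_b"))


# ---------------------------------------------------------------------------
# per-patient simulation
# ---------------------------------------------------------------------------

def _coding_positions(genes: Sequence[GeneModel]) -> Tuple[np.ndarray, np.ndarray, List[str], np.ndarray]:
    """All coding positions as (chrom_index, pos) arrays plus the gene of each position."""
    chroms: List[str] = []
    chrom_idx_parts, pos_parts, gene_parts = [], [], []
    for g_i, gm in enumerate(genes):
        for chrom, s, e in gm.intervals.intervals:
            if chrom not in chroms:
                chroms.append(chrom)
            ci = chroms.index(chrom)
            p = np.arange(s + 1, e + 1)
            chrom_idx_parts.append(np.full(len(p), ci))
            pos_parts.append(p)
            gene_parts.append(np.full(len(p), g_i))
    return (np.concatenate(chrom_idx_parts), np.concatenate(pos_parts),
            chroms, np.concatenate(gene_parts))


def _make_qual(rng: np.random.Generator, alt_depth: int) -> float:
    q = QUAL_BASE + QUAL_PER_ALT_READ * alt_depth + rng.normal(0.0, QUAL_SD)
    return round(max(1.0, q), 1)


def _simulate_patient(pid: str, cfg: CohortConfig, thr: ThresholdConfig,
                      genes: Sequence[GeneModel], capture_a: IntervalSet,
                      capture_b: IntervalSet, has_rna: bool,
                      rng: np.random.Generator) -> Tuple[PatientTruth, PatientData]:
    chrom_idx, positions, chroms, gene_of_pos = _coding_positions(genes)
    n_pos = len(positions)
    n_sites = cfg.n_germline_sites + cfg.n_somatic
    if n_sites > n_pos:
        raise ValueError(
            f"target space too small: {n_sites} variant sites requested over "
            f"{n_pos} coding positions")

    site_idx = rng.choice(n_pos, size=n_sites, replace=False)
    site_idx.sort()
    is_somatic = np.zeros(n_sites, dtype=bool)
    is_somatic[rng.choice(n_sites, size=cfg.n_somatic, replace=False)] = True

    refs = _BASES[rng.integers(0, 4, size=n_sites)]
    germline: List[TruthVariant] = []
    somatic: List[TruthVariant] = []
    site_gene: List[int] = []
    truth_variants: List[TruthVariant] = []
    for i in range(n_sites):
        chrom = chroms[chrom_idx[site_idx[i]]]
        pos = int(positions[site_idx[i]])
        ref = str(refs[i])
        alt = _alt_allele(rng, ref, cfg.ts_prob)
        if is_somatic[i]:
            tv = TruthVariant(chrom, pos, ref, alt, "het")
            somatic.append(tv)
        else:
            zyg = "het" if rng.random() < cfg.het_fraction else "hom"
            tv = TruthVariant(chrom, pos, ref, alt, zyg)
            germline.append(tv)
        truth_variants.append(tv)
        site_gene.append(int(gene_of_pos[site_idx[i]]))

    # --- per-assay depth fields ----------------------------------------
    depth_fields: Dict[str, _DesignDepths] = {
        "wga_tumor": _DesignDepths(rng, capture_a, cfg.depth_mean_wga, cfg.wga_dispersion),
        "wga_normal": _DesignDepths(rng, capture_a, cfg.depth_mean_wga, cfg.wga_dispersion),
        "unamplified_tumor": _DesignDepths(rng, capture_b, cfg.depth_mean_unamp,
                                           cfg.unamp_dispersion),
    }

    callsets: Dict[str, Callset] = {}
    evidence: Dict[str, Callset] = {}
    coverage: Dict[str, CoverageTrack] = {}
    fp_truth: Dict[str, List[Tuple[str, int, str]]] = {}
    lost_truth: Dict[str, List[Tuple[str, int, str]]] = {}
    tohom_truth: Dict[str, List[Tuple[str, int, str]]] = {}

    occupied_by_chrom: Dict[str, np.ndarray] = {}
    for tv in truth_variants:
        occupied_by_chrom.setdefault(tv.chrom, []).append(tv.pos)  # type: ignore[arg-type]
    occupied_by_chrom = {c: np.sort(np.array(v)) for c, v in occupied_by_chrom.items()}

    for assay in DNA_ASSAYS:
        field_ = depth_fields[assay]
        include_somatic = assay in TUMOR_ASSAYS
        is_wga = assay in WGA_ASSAYS
        lost: List[Tuple[str, int, str]] = []
        to_hom: List[Tuple[str, int, str]] = []
        filtered_calls: List[VariantCall] = []
        evidence_calls: List[VariantCall] = []

        for tv, som in zip(truth_variants, is_somatic):
            if som and not include_somatic:
                continue
            depth = field_.depth_at(tv.chrom, tv.pos)
            if depth == 0:
                continue
            zyg = tv.zygosity
            if is_wga and zyg == "het":
                u = rng.random()
                if u < cfg.dropout_prob / 2.0:
                    lost.append(tv.key)
                    continue
                if u < cfg.dropout_prob:
                    to_hom.append(tv.key)
                    zyg = "hom"
            if zyg == "het":
                vaf = 0.5 * cfg.purity if som else 0.5
            else:
                vaf = HOM_ALT_VAF
            alt_depth = int(rng.binomial(depth, vaf))
            if alt_depth == 0:
                continue
            qual = _make_qual(rng, alt_depth)
            call = VariantCall(tv.chrom, tv.pos, tv.ref, tv.alt,
                               "het" if zyg == "het" else "hom_alt",
                               depth, alt_depth, qual)
            evidence_calls.append(call)
            if depth >= thr.min_call_depth and qual > thr.min_call_qual:
                filtered_calls.append(call)

        fps: List[Tuple[str, int, str]] = []
        if is_wga and cfg.wga_fp_rate > 0:
            design = capture_a
            lam = cfg.wga_fp_rate * design.total_length() / 1e6
            n_fp = int(rng.poisson(lam))
            # candidate positions: adequately covered, not already a truth site
            cand_chrom: List[str] = []
            cand_pos: List[np.ndarray] = []
            cand_dep: List[np.ndarray] = []
            for chrom in design.chroms:
                pos_arr, dep_arr = field_.arrays[chrom]
                ok = dep_arr >= thr.min_call_depth
                occ = occupied_by_chrom.get(chrom)
                if occ is not None and len(occ):
                    ok &= ~np.isin(pos_arr, occ)
                cand_chrom.extend([chrom] * int(ok.sum()))
                cand_pos.append(pos_arr[ok])
                cand_dep.append(dep_arr[ok])
            cand_pos_all = np.concatenate(cand_pos) if cand_pos else np.zeros(0, int)
            cand_dep_all = np.concatenate(cand_dep) if cand_dep else np.zeros(0, int)
            n_fp = min(n_fp, len(cand_pos_all))
            chosen = rng.choice(len(cand_pos_all), size=n_fp, replace=False)
            for ci in sorted(chosen.tolist()):
                chrom = cand_chrom[ci]
                pos = int(cand_pos_all[ci])
                depth = int(cand_dep_all[ci])
                ref = str(_BASES[rng.integers(0, 4)])
                alt = str(_BASES[rng.integers(0, 4)])
                while alt == ref:
                    alt = str(_BASES[rng.integers(0, 4)])
                vaf = rng.uniform(0.15, 0.35)
                alt_depth = max(1, int(rng.binomial(depth, vaf)))
                qual = max(round(thr.min_call_qual + 1.0, 1), _make_qual(rng, alt_depth))
                call = VariantCall(chrom, pos, ref, alt, "het", depth,
                                   min(alt_depth, depth), qual)
                evidence_calls.append(call)
                filtered_calls.append(call)
                fps.append(call.key)

        callsets[assay] = Callset(pid, assay, tuple(filtered_calls))
        evidence[assay] = Callset(pid, assay, tuple(evidence_calls))
        coverage[assay] = field_.track(pid, assay)
        fp_truth[assay] = fps
        lost_truth[assay] = lost
        tohom_truth[assay] = to_hom

    # --- RNA ------------------------------------------------------------
    gene_class: Dict[str, str] = {}
    fpkm: Dict[str, float] = {}
    expression: Optional[ExpressionTable] = None
    if has_rna:
        mono_coin = rng.random(len(genes))
        expr_coin = rng.random(len(genes))
        for g_i, gm in enumerate(genes):
            if expr_coin[g_i] < cfg.rna_expressed_fraction:
                fpkm[gm.gene_id] = float(rng.lognormal(cfg.fpkm_lognorm_mu,
                                                       cfg.fpkm_lognorm_sigma))
                gene_class[gm.gene_id] = ("mono" if mono_coin[g_i] < cfg.rna_monoallelic_fraction
                                          else "bi")
            else:
                fpkm[gm.gene_id] = float(rng.uniform(0.0, 0.5))
                gene_class[gm.gene_id] = "silent"
        expression = ExpressionTable(rows=dict(fpkm))

        gene_depth_mean = {gm.gene_id: cfg.rna_depth_per_fpkm * fpkm[gm.gene_id]
                           for gm in genes}
        by_chrom_pos: Dict[str, List[np.ndarray]] = {}
        by_chrom_dep: Dict[str, List[np.ndarray]] = {}
        for gm in genes:
            for chrom, s, e in gm.intervals.intervals:
                p = np.arange(s + 1, e + 1)
                d = _negbin(rng, gene_depth_mean[gm.gene_id], cfg.rna_dispersion, len(p))
                by_chrom_pos.setdefault(chrom, []).append(p)
                by_chrom_dep.setdefault(chrom, []).append(d)
        rna_field = _DesignDepths.__new__(_DesignDepths)
        rna_field.arrays = {}
        for chrom in by_chrom_pos:
            p = np.concatenate(by_chrom_pos[chrom])
            d = np.concatenate(by_chrom_dep[chrom])
            order = np.argsort(p, kind="stable")
            rna_field.arrays[chrom] = (p[order], d[order])
        coverage["rna_tumor"] = rna_field.track(pid, "rna_tumor")

        rna_calls: List[VariantCall] = []
        for tv, g_i in zip(truth_variants, site_gene):
            gm = genes[g_i]
            cls = gene_class[gm.gene_id]
            if cls == "silent":
                pass  # depth will be low; fall through and let the filter act
            depth = rna_field.depth_at(tv.chrom, tv.pos)
            if depth == 0:
                continue
            if tv.zygosity == "hom":
                vaf, gt = HOM_ALT_VAF, "hom_alt"
            elif cls == "mono":
                # one haplotype expressed; unphased truth -> fair coin per site
                if rng.random() < 0.5:
                    continue  # reference haplotype expressed: no variant evidence
                vaf, gt = HOM_ALT_VAF, "hom_alt"
            else:
                vaf, gt = 0.5, "het"
            alt_depth = int(rng.binomial(depth, vaf))
            if alt_depth == 0:
                continue
            qual = _make_qual(rng, alt_depth)
            if depth >= thr.min_call_depth and qual > thr.min_call_qual:
                rna_calls.append(VariantCall(tv.chrom, tv.pos, tv.ref, tv.alt,
                                             gt, depth, alt_depth, qual))
        callsets["rna_tumor"] = Callset(pid, "rna_tumor", tuple(rna_calls))

    truth = PatientTruth(patient_id=pid, germline=germline, somatic=somatic,
                         false_positives=fp_truth, dropout_lost=lost_truth,
                         dropout_to_hom=tohom_truth, gene_class=gene_class,
                         fpkm=fpkm, has_rna=has_rna)
    data = PatientData(patient_id=pid, callsets=callsets, evidence=evidence,
                       coverage=coverage, expression=expression, has_rna=has_rna)
    return truth, data


# ---------------------------------------------------------------------------
# cohort-level API
# ---------------------------------------------------------------------------

def simulate_cohort(config: CohortConfig,
                    outdir: str | Path | None = None,
                    thresholds: ThresholdConfig | None = None) -> SimulatedCohort:
    """Simulate the cohort; if ``outdir`` is given also write the full file tree.

    The same config and seed produce a byte-identical tree.
    """
    thr = thresholds or ThresholdConfig()
    ss = np.random.SeedSequence(config.seed)
    cohort_seed, *patient_seeds = ss.spawn(config.n_patients + 1)
    cohort_rng = np.random.default_rng(cohort_seed)

    genes = _build_genes(config)
    capture_a, capture_b = _build_captures(config, genes, cohort_rng)
    coding = IntervalSet(
        (iv for gm in genes for iv in gm.intervals.intervals), label="coding")

    rna_ids = set(range(min(config.n_rna_patients, config.n_patients)))
    patients: Dict[str, PatientData] = {}
    truths: Dict[str, PatientTruth] = {}
    for i in range(config.n_patients):
        pid = f"P{i + 1:02d}"
        rng = np.random.default_rng(patient_seeds[i])
        truth, data = _simulate_patient(pid, config, thr, genes, capture_a,
                                        capture_b, i in rna_ids, rng)
        truths[pid] = truth
        patients[pid] = data
        logger.info("simulated %s: %d germline, %d somatic, rna=%s",
                    pid, len(truth.germline), len(truth.somatic), truth.has_rna)

    cohort = SimulatedCohort(config=config, thresholds=thr,
                             truth=TruthSet(patients=truths), genes=genes,
                             capture_a=capture_a, capture_b=capture_b,
                             coding=coding, patients=patients)
    if outdir is not None:
        write_cohort(cohort, outdir)
    return cohort


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> None:
    """Write the cohort file tree: cohort-level BEDs plus per-patient VCFs/TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = dict(cohort.config.genome)
    write_bed(cohort.capture_a, outdir / "capture_a.bed")
    write_bed(cohort.capture_b, outdir / "capture_b.bed")
    write_bed(cohort.coding, outdir / "coding.bed")
    write_gene_models(cohort.genes, outdir / "genes.bed")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cohort.config.to_dict(), fh, sort_keys=True)
    truth_report(cohort.truth).to_csv(outdir / "truth_report.tsv", sep="\t", index=False)

    for pid in sorted(cohort.patients):
        pdata = cohort.patients[pid]
        pdir = outdir / f"patient_{pid}"
        pdir.mkdir(exist_ok=True)
        for assay, cs in sorted(pdata.callsets.items()):
            write_vcf(cs, pdir / f"{assay}.vcf", contigs=contigs)
        for assay, cs in sorted(pdata.evidence.items()):
            write_vcf(cs, pdir / f"{assay}.evidence.vcf", contigs=contigs)
        for assay, track in sorted(pdata.coverage.items()):
            write_coverage_tsv(track, pdir / f"{assay}.coverage.tsv")
        if pdata.expression is not None:
            write_expression_tsv(pdata.expression, pdir / "expression.tsv")


def truth_report(truth: TruthSet) -> pd.DataFrame:
    """Per-patient counts of germline/somatic variants, injected FPs and dropouts."""
    rows = []
    for pid in sorted(truth.patients):
        pt = truth.patients[pid]
        n_het = sum(1 for tv in pt.germline if tv.zygosity == "het")
        rows.append({
            "patient_id": pid,
            "n_germline": len(pt.germline),
            "n_germline_het": n_het,
            "n_germline_hom": len(pt.germline) - n_het,
            "n_somatic": len(pt.somatic),
            "n_fp_wga_tumor": len(pt.false_positives.get("wga_tumor", [])),
            "n_fp_wga_normal": len(pt.false_positives.get("wga_normal", [])),
            "n_dropout_wga_tumor": (len(pt.dropout_lost.get("wga_tumor", []))
                                    + len(pt.dropout_to_hom.get("wga_tumor", []))),
            "n_dropout_wga_normal": (len(pt.dropout_lost.get("wga_normal", []))
                                     + len(pt.dropout_to_hom.get("wga_normal", []))),
            "n_genes_expressed": sum(1 for c in pt.gene_class.values() if c != "silent"),
            "n_genes_monoallelic": sum(1 for c in pt.gene_class.values() if c == "mono"),
        })
    return pd.DataFrame(rows)
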