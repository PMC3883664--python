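"""Domain data model and readers/writers for the standard formats the pipeline touches.

The pipeline compares single-nucleotide variant (SNV) call sets obtained from
whole-genome-amplified (WGA) and unamplified exome capture of the same tumor,
plus matched WGA normal tissue and tumor RNA-seq.  This module defines the
in-memory containers (variant calls, per-base coverage tracks, genomic interval
sets, expression tables) and minimal, strict readers/writers for the on-disk
contracts:

* VCF v4.2 subset (``GT:DP:AD`` per-sample format) via :mod:`pysam`;
* BED3 (capture designs, coding regions) and BED4 (gene models);
* coverage TSV ``chrom<TAB>pos(1-based)<TAB>depth`` (absent position = depth 0);
* expression TSV ``gene_id<TAB>fpkm`` with a header line.

Coordinate conventions follow the two standards they come from: variants are
1-based (VCF), intervals are 0-based half-open (BED).  A 1-based position ``p``
falls in interval ``(s, e)`` iff ``s < p <= e`` — this is the single place the
two conventions meet.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

ASSAYS = ("wga_tumor", "wga_normal", "unamplified_tumor", "rna_tumor")

_BASES = frozenset("ACGT")
_TRANSITION_PAIRS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})

VariantKey = Tuple[str, int, str]


def is_transition(ref: str, alt: str) -> bool:
    """True for A<->G and C<->T substitutions (purine-purine / pyrimidine-pyrimidine)."""
    return (ref, alt) in _TRANSITION_PAIRS


@dataclass(frozen=True)
class VariantCall:
    """One called SNV with genotype class, read depths and phred-scaled quality.

    ``depth`` is the total read depth at the site and ``alt_depth`` the number
    of reads supporting the alternate allele, so ``alt_depth / depth`` is the
    variant allele fraction (VAF).
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotype: str  # "het" | "hom_alt"
    depth: int
    alt_depth: int
    qual: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"SNV only: ref={self.ref!r} alt={self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.genotype not in ("het", "hom_alt"):
            raise ValueError(f"genotype must be het/hom_alt, got {self.genotype!r}")
        if self.depth < 0 or self.alt_depth < 0 or self.alt_depth > self.depth:
            raise ValueError(
                f"require 0 <= alt_depth <= depth, got {self.alt_depth}/{self.depth}"
            )
        if self.qual < 0:
            raise ValueError(f"qual must be >= 0, got {self.qual}")

    @property
    def key(self) -> VariantKey:
        """Match key used throughout the pipeline: (chrom, pos, alt)."""
        return (self.chrom, self.pos, self.alt)

    @property
    def vaf(self) -> float:
        """Variant allele fraction alt_depth/depth (nan at zero depth)."""
        return self.alt_depth / self.depth if self.depth > 0 else math.nan

    @property
    def is_transition(self) -> bool:
        return is_transition(self.ref, self.alt)


@dataclass(frozen=True)
class Callset:
    """An SNV call set for one sample/assay, sorted by (chrom, pos, alt), unique per key."""

    sample_id: str
    assay: str
    calls: Tuple[VariantCall, ...] = ()

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        ordered = tuple(sorted(self.calls, key=lambda c: c.key))
        keys = [c.key for c in ordered]
        if len(set(keys)) != len(keys):
            seen: set = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate call key {k} in callset {self.sample_id}")
                seen.add(k)
        object.__setattr__(self, "calls", ordered)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self.calls)

    def keys(self) -> frozenset:
        return frozenset(c.key for c in self.calls)

    def by_key(self) -> Dict[VariantKey, VariantCall]:
        return {c.key: c for c in self.calls}

    def with_calls(self, calls: Iterable[VariantCall]) -> "Callset":
        return replace(self, calls=tuple(calls))


class IntervalSet:
    """A set of genomic intervals in 0-based half-open coordinates.

    Stored normalized: per chromosome, sorted, with overlapping or bookended
    intervals merged.  Normalization is idempotent and order-independent.
    """

    __slots__ = ("label", "_ivs")

    def __init__(self, intervals: Iterable[Tuple[str, int, int]] = (), label: str = ""):
        self.label = label
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            start, end = int(start), int(end)
            if start < 0:
                raise ValueError(f"negative interval start {chrom}:{start}-{end}")
            if end <= start:
                raise ValueError(f"interval end must exceed start: {chrom}:{start}-{end}")
            by_chrom.setdefault(str(chrom), []).append((start, end))
        merged: Dict[str, List[Tuple[int, int]]] = {}
        for chrom in sorted(by_chrom):
            out: List[Tuple[int, int]] = []
            for s, e in sorted(by_chrom[chrom]):
                if out and s <= out[-1][1]:  # overlap or bookended
                    out[-1] = (out[-1][0], max(out[-1][1], e))
                else:
                    out.append((s, e))
            merged[chrom] = out
        self._ivs = merged

    @property
    def intervals(self) -> List[Tuple[str, int, int]]:
        return [(c, s, e) for c in sorted(self._ivs) for s, e in self._ivs[c]]

    @property
    def chroms(self) -> List[str]:
        return sorted(self._ivs)

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position: true iff some interval (s,e) has s < pos <= e."""
        ivs = self._ivs.get(chrom)
        if not ivs:
            return False
        starts = [s for s, _ in ivs]
        i = bisect_right(starts, pos - 1) - 1  # rightmost interval with s <= pos-1
        return i >= 0 and pos <= ivs[i][1]

    def intersect(self, other: "IntervalSet", label: str = "") -> "IntervalSet":
        """Interval-by-interval intersection via a linear sweep per chromosome."""
        out: List[Tuple[str, int, int]] = []
        for chrom in self._ivs:
            a = self._ivs[chrom]
            b = other._ivs.get(chrom)
            if not b:
                continue
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i][0], b[j][0])
                e = min(a[i][1], b[j][1])
                if s < e:
                    out.append((chrom, s, e))
                if a[i][1] <= b[j][1]:
                    i += 1
                else:
                    j += 1
        return IntervalSet(out, label=label or f"({self.label})&({other.label})")

    def total_length(self) -> int:
        return sum(e - s for ivs in self._ivs.values() for s, e in ivs)

    def positions(self, chrom: str) -> np.ndarray:
        """All 1-based positions on one chromosome covered by this set."""
        parts = [np.arange(s + 1, e + 1) for s, e in self._ivs.get(chrom, [])]
        return np.concatenate(parts) if parts else np.array([], dtype=int)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, IntervalSet) and self._ivs == other._ivs

    def __hash__(self) -> int:
        return hash(tuple(self.intervals))

    def __bool__(self) -> bool:
        return bool(self._ivs)

    def __len__(self) -> int:
        return sum(len(v) for v in self._ivs.values())

    def __repr__(self) -> str:
        return f"IntervalSet({self.label!r}, n={len(self)}, bp={self.total_length()})"


class CoverageTrack:
    """Per-base read depth for one sample/assay.

    Stands in for the unfiltered alignment: rescue and RNA checks query depth at
    arbitrary positions.  Positions absent from the track have depth 0, but a
    chromosome entirely absent is distinguishable (``has_chrom``) so that a
    truncated track can be rejected rather than silently read as zero coverage.
    """

    def __init__(self, sample_id: str, assay: str,
                 arrays: Mapping[str, Tuple[np.ndarray, np.ndarray]]):
        if assay not in ASSAYS:
            raise ValueError(f"unknown assay {assay!r}")
        self.sample_id = sample_id
        self.assay = assay
        self._arr: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, depth) in arrays.items():
            pos = np.asarray(pos, dtype=np.int64)
            depth = np.asarray(depth, dtype=np.int64)
            if np.any(depth < 0):
                raise ValueError(f"negative depth on {chrom}")
            order = np.argsort(pos, kind="stable")
            self._arr[str(chrom)] = (pos[order], depth[order])

    @classmethod
    def from_pairs(cls, sample_id: str, assay: str,
                   depth_map: Mapping[Tuple[str, int], int]) -> "CoverageTrack":
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for (chrom, pos), d in depth_map.items():
            by_chrom.setdefault(chrom, []).append((pos, d))
        arrays = {
            c: (np.array([p for p, _ in v]), np.array([d for _, d in v]))
            for c, v in by_chrom.items()
        }
        return cls(sample_id, assay, arrays)

    @property
    def chroms(self) -> List[str]:
        return sorted(self._arr)

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._arr

    def depth(self, chrom: str, pos: int) -> int:
        entry = self._arr.get(chrom)
        if entry is None:
            return 0
        positions, depths = entry
        i = np.searchsorted(positions, pos)
        if i < len(positions) and positions[i] == pos:
            return int(depths[i])
        return 0

    def depths_at(self, sites: Sequence[Tuple[str, int]]) -> np.ndarray:
        return np.array([self.depth(c, p) for c, p in sites], dtype=np.int64)

    def sum_over(self, targets: IntervalSet) -> int:
        """Total depth summed over all target positions."""
        total = 0
        for chrom, start, end in targets.intervals:
            entry = self._arr.get(chrom)
            if entry is None:
                continue
            positions, depths = entry
            lo = np.searchsorted(positions, start + 1)  # 1-based positions in (start, end]
            hi = np.searchsorted(positions, end, side="right")
            total += int(depths[lo:hi].sum())
        return total

    def items(self) -> Iterator[Tuple[str, int, int]]:
        for chrom in sorted(self._arr):
            positions, depths = self._arr[chrom]
            for p, d in zip(positions.tolist(), depths.tolist()):
                yield chrom, p, d


@dataclass(frozen=True)
class ExpressionTable:
    """Gene-level expression, gene_id -> FPKM."""

    rows: Mapping[str, float]

    def __post_init__(self) -> None:
        for g, f in self.rows.items():
            if f < 0:
                raise ValueError(f"negative FPKM for {g}: {f}")

    def fpkm(self, gene_id: str) -> float:
        return float(self.rows[gene_id])

    def __len__(self) -> int:
        return len(self.rows)

    def items(self):
        return self.rows.items()


@dataclass(frozen=True)
class GeneModel:
    """Genomic footprint of one gene; the simulator never emits overlapping genes."""

    gene_id: str
    intervals: IntervalSet


@dataclass(frozen=True)
class ThresholdConfig:
    """All analysis cutoffs in one auditable place.

    ``min_call_depth`` operationalizes the ">10-fold coverage" calling rule as
    depth >= 11, and ``low_cov_threshold`` the "coverage < 10" rescue rule as
    depth <= 9; depth exactly 10 passes neither and is reported as a separate
    coverage-gap category.
    """

    min_call_depth: int = 11
    min_call_qual: float = 30.0
    low_cov_threshold: int = 10
    het_hom_exclusion: float = 3.0
    minor_allele_min: float = 0.20
    fpkm_min: float = 1.0
    fpkm_transcript_min: float = 2.8
    expressed_quantile: float = 0.75

    def __post_init__(self) -> None:
        for name in ("min_call_depth", "min_call_qual", "low_cov_threshold",
                     "het_hom_exclusion", "minor_allele_min", "fpkm_min",
                     "fpkm_transcript_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.expressed_quantile <= 1):
            raise ValueError("expressed_quantile must be in (0, 1]")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _vcf_header(sample_id: str, assay: str,
                contigs: Mapping[str, int] | Iterable[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    if isinstance(contigs, Mapping):
        for name, length in contigs.items():
            header.add_line(f"##contig=<ID={name},length={length}>")
    else:
        for name in contigs:
            header.add_line(f"##contig=<ID={name}>")
    header.add_line(f"##assay={assay}")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.add_sample(sample_id)
    return header


def write_vcf(callset: Callset, path: str | Path,
              contigs: Mapping[str, int] | None = None) -> None:
    """Write a callset as a VCF v4.2 file with GT:DP:AD genotypes.

    ``contigs`` supplies header contig lengths; when omitted the contigs seen in
    the calls are declared without lengths.
    """
    path = Path(path)
    if contigs is None:
        contigs = sorted({c.chrom for c in callset.calls})
    header = _vcf_header(callset.sample_id, callset.assay, contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for call in callset.calls:
            rec = vf.new_record(contig=call.chrom, start=call.pos - 1,
                                alleles=(call.ref, call.alt), qual=call.qual)
            fmt = rec.samples[callset.sample_id]
            fmt["GT"] = (0, 1) if call.genotype == "het" else (1, 1)
            fmt.phased = False
            fmt["DP"] = call.depth
            fmt["AD"] = (call.depth - call.alt_depth, call.alt_depth)
            vf.write(rec)


def read_vcf(path: str | Path, sample_id: str | None = None,
             assay: str | None = None) -> Callset:
    """Read a VCF into a Callset of bi-allelic SNV calls.

    Multi-allelic records are decomposed into one call per alternate allele
    present in the genotype; the genotype is ``het`` when the two GT alleles
    differ and ``hom_alt`` when both are the same alternate.  Records whose ref
    or alt is not a single base (indels, MNVs) are skipped and counted in the
    log, never silently dropped.  Quality is quantized to 0.01 (VCF QUAL is
    stored as a 32-bit float by htslib).
    """
    path = Path(path)
    skipped = 0
    calls: List[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        if assay is None:
            assay_lines = [r.value for r in vf.header.records if r.key == "assay"]
            assay = assay_lines[0] if assay_lines else None
        if assay is None:
            raise ValueError(f"{path}: no ##assay header line and no assay given")
        samples = list(vf.header.samples)
        if sample_id is None:
            if len(samples) != 1:
                raise ValueError(f"{path}: expected exactly one sample, got {samples}")
            sample_id = samples[0]
        for rec in vf:
            if "GT" not in rec.format:
                raise ValueError(f"{path}: record {rec.chrom}:{rec.pos} has no GT field")
            fmt = rec.samples[sample_id]
            gt = tuple(a for a in fmt["GT"] if a is not None)
            dp = fmt.get("DP")
            ad = fmt.get("AD")
            if dp is None or ad is None:
                raise ValueError(f"{path}: record {rec.chrom}:{rec.pos} lacks DP/AD")
            if len(rec.ref) != 1 or rec.ref not in _BASES:
                skipped += 1
                continue
            alt_indices = sorted({a for a in gt if a and a > 0})
            emitted_any = False
            genotype = "het" if len(set(gt)) > 1 else "hom_alt"
            for idx in alt_indices:
                alt = rec.alts[idx - 1]
                if len(alt) != 1 or alt not in _BASES:
                    continue
                calls.append(VariantCall(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    genotype=genotype, depth=int(dp), alt_depth=int(ad[idx]),
                    qual=round(float(rec.qual), 2) if rec.qual is not None else 0.0,
                ))
                emitted_any = True
            if alt_indices and not emitted_any:
                skipped += 1
    if skipped:
        logger.info("read_vcf(%s): skipped %d non-SNV records", path.name, skipped)
    return Callset(sample_id=sample_id, assay=assay, calls=tuple(calls))


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, label: str | None = None) -> IntervalSet:
    """Read a BED3 file into a normalized IntervalSet; start >= end is a hard error."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                         names=["chrom", "start", "end"],
                         dtype={"chrom": str, "start": int, "end": int})
    except pd.errors.EmptyDataError:
        return IntervalSet([], label=label or path.stem)
    return IntervalSet(df.itertuples(index=False, name=None), label=label or path.stem)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_gene_models(path: str | Path) -> List[GeneModel]:
    """Read a BED4 gene-model file (chrom, start, end, gene_id) into GeneModels."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "gene_id"],
                         dtype={"chrom": str, "start": int, "end": int, "gene_id": str})
    except pd.errors.EmptyDataError:
        return []
    models = []
    for gene_id, grp in df.groupby("gene_id", sort=True):
        ivs = IntervalSet(grp[["chrom", "start", "end"]].itertuples(index=False, name=None),
                          label=gene_id)
        models.append(GeneModel(gene_id=gene_id, intervals=ivs))
    return models


def write_gene_models(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gm in models:
            for chrom, start, end in gm.intervals.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\t{gm.gene_id}\n")


def read_coverage_tsv(path: str | Path, sample_id: str, assay: str) -> CoverageTrack:
    """Read a ``chrom<TAB>pos<TAB>depth`` track; negative depth is a hard error."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "depth"],
                         dtype={"chrom": str, "pos": np.int64, "depth": np.int64})
    except pd.errors.EmptyDataError:
        return CoverageTrack(sample_id, assay, {})
    if (df["depth"] < 0).any():
        bad = df[df["depth"] < 0].iloc[0]
        raise ValueError(f"{path}: negative depth at {bad.chrom}:{bad.pos}")
    arrays = {
        chrom: (grp["pos"].to_numpy(), grp["depth"].to_numpy())
        for chrom, grp in df.groupby("chrom", sort=True)
    }
    return CoverageTrack(sample_id, assay, arrays)


def write_coverage_tsv(track: CoverageTrack, path: str | Path) -> None:
    frames = []
    for chrom in track.chroms:
        positions, depths = track._arr[chrom]
        frames.append(pd.DataFrame({"chrom": chrom, "pos": positions, "depth": depths}))
    df = (pd.concat(frames, ignore_index=True) if frames
          else pd.DataFrame(columns=["chrom", "pos", "depth"]))
    df.to_csv(path, sep="\t", header=False, index=False)


def read_expression_tsv(path: str | Path) -> ExpressionTable:
    """Read a ``gene_id<TAB>fpkm`` table (with header); negative FPKM is a hard error."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "fpkm": float})
    if list(df.columns) != ["gene_id", "fpkm"]:
        raise ValueError(f"{path}: expected header 'gene_id<TAB>fpkm', got {list(df.columns)}")
    if (df["fpkm"] < 0).any():
        raise ValueError(f"{path}: negative FPKM values present")
    return ExpressionTable(rows=dict(zip(df["gene_id"], df["fpkm"])))


def write_expression_tsv(expr: ExpressionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfpkm\n")
        for gene_id in sorted(expr.rows):
            fh.write(f"{gene_id}\t{expr.rows[gene_id]:.6g}\n")
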