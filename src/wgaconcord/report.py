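"""Cohort-level aggregation: per-patient analysis rows plus average/SD summary rows.

``run_pipeline`` consumes a cohort directory (as written by the simulator, or
assembled by a user from real files in the same layout) and chains the stages:
per-sample QC -> anomalous-sample exclusion -> shared-target concordance
partition -> rescue of discordant calls against unfiltered evidence -> somatic
subtraction and confirmation -> RNA validation.  Patients with an excluded DNA
sample drop out of every cross-method comparison; patients without RNA
contribute to the DNA columns but are missing from RNA columns, and column
averages are taken over non-missing entries only.

All outputs are TSV with documented headers; percentage columns state their
denominator convention.  Report averages are recomputed from the per-patient
rows at report time as an internal consistency check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import concordance as conc
from . import rna_validation as rnaval
from . import sample_qc as qc
from . import somatic as som
from .rescue import interpret as rescue_interpret
from .rescue import rescue as rescue_classify
from .formats_io import (Callset, CoverageTrack, GeneModel, IntervalSet,
                         ThresholdConfig, read_bed, read_coverage_tsv,
                         read_expression_tsv, read_gene_models, read_vcf)
from .util import round_half_away

logger = logging.getLogger(__name__)

DNA_ASSAYS = ("wga_tumor", "wga_normal", "unamplified_tumor")


def column_average(values: Sequence[float]) -> Tuple[float, float]:
    """Mean and sample SD over non-missing (non-nan) entries.

    All-missing input raises; a single value yields (value, nan) with the SD
    flagged undefined in the log.
    """
    arr = np.asarray([v for v in values if not (isinstance(v, float) and math.isnan(v))],
                     dtype=float)
    if arr.size == 0:
        raise ValueError("column_average: all values missing")
    mean = float(arr.mean())
    if arr.size < 2:
        logger.warning("column_average: single value, SD undefined")
        return mean, math.nan
    return mean, float(arr.std(ddof=1))


@dataclass
class PatientInputs:
    """Everything read from one patient directory."""

    patient_id: str
    callsets: Dict[str, Callset]
    evidence: Dict[str, Callset]
    coverage: Dict[str, CoverageTrack]
    expression: Optional[object]
    has_rna: bool


@dataclass
class CohortReport:
    qc_table: pd.DataFrame
    concordance_table: pd.DataFrame
    discordance_table: pd.DataFrame
    excluded_patients: List[str]
    partitions: Dict[str, conc.ConcordancePartition] = field(default_factory=dict)
    somatic_sets: Dict[str, som.SomaticCallset] = field(default_factory=dict)


def read_patient_dir(pdir: Path) -> PatientInputs:
    pid = pdir.name.removeprefix("patient_")
    callsets: Dict[str, Callset] = {}
    evidence: Dict[str, Callset] = {}
    coverage: Dict[str, CoverageTrack] = {}
    for assay in DNA_ASSAYS:
        vcf = pdir / f"{assay}.vcf"
        if not vcf.exists():
            raise FileNotFoundError(f"patient {pid}: missing {assay}.vcf")
        callsets[assay] = read_vcf(vcf)
        ev = pdir / f"{assay}.evidence.vcf"
        if not ev.exists():
            raise FileNotFoundError(f"patient {pid}: missing {assay}.evidence.vcf")
        evidence[assay] = read_vcf(ev)
        cov = pdir / f"{assay}.coverage.tsv"
        if not cov.exists():
            raise FileNotFoundError(f"patient {pid}: missing {assay}.coverage.tsv")
        coverage[assay] = read_coverage_tsv(cov, pid, assay)
    has_rna = (pdir / "rna_tumor.vcf").exists()
    expression = None
    if has_rna:
        callsets["rna_tumor"] = read_vcf(pdir / "rna_tumor.vcf")
        coverage["rna_tumor"] = read_coverage_tsv(pdir / "rna_tumor.coverage.tsv",
                                                  pid, "rna_tumor")
        expression = read_expression_tsv(pdir / "expression.tsv")
    return PatientInputs(patient_id=pid, callsets=callsets, evidence=evidence,
                         coverage=coverage, expression=expression, has_rna=has_rna)


def _append_summary_rows(df: pd.DataFrame, id_col: str,
                         round_digits: Dict[str, int]) -> pd.DataFrame:
    """Append Average and StDev rows over the numeric columns (nan-skipping)."""
    numeric = [c for c in df.columns if c != id_col and
               pd.api.types.is_numeric_dtype(df[c])]
    avg_row = {id_col: "Average"}
    sd_row = {id_col: "StDev"}
    for col in numeric:
        values = df[col].tolist()
        try:
            mean, sd = column_average(values)
        except ValueError:
            mean, sd = math.nan, math.nan
        nd = round_digits.get(col, 2)
        avg_row[col] = round_half_away(mean, nd) if not math.isnan(mean) else mean
        sd_row[col] = round_half_away(sd, nd) if not math.isnan(sd) else sd
    out = pd.concat([df, pd.DataFrame([avg_row, sd_row])], ignore_index=True)
    # internal consistency: the Average row must recompute from the patient rows
    for col in numeric:
        try:
            mean, _ = column_average(df[col].tolist())
        except ValueError:
            continue
        expect = round_half_away(mean, round_digits.get(col, 2))
        got = out.loc[out[id_col] == "Average", col].iloc[0]
        if not math.isnan(expect) and got != expect:
            raise AssertionError(f"summary row inconsistent for {col}: {got} != {expect}")
    return out


def run_pipeline(input_dir: str | Path, thresholds: ThresholdConfig | None = None,
                 outdir: str | Path | None = None) -> CohortReport:
    """Run qc -> concordance -> rescue -> somatic -> rna for every patient directory."""
    input_dir = Path(input_dir)
    thr = thresholds or ThresholdConfig()

    capture_a = read_bed(input_dir / "capture_a.bed", label="capture_a")
    capture_b = read_bed(input_dir / "capture_b.bed", label="capture_b")
    coding = read_bed(input_dir / "coding.bed", label="coding")
    genes: List[GeneModel] = read_gene_models(input_dir / "genes.bed")
    space = conc.shared_target_space(capture_a, capture_b, coding)

    pdirs = sorted(p for p in input_dir.iterdir()
                   if p.is_dir() and p.name.startswith("patient_"))
    if not pdirs:
        raise FileNotFoundError(f"no patient_* directories under {input_dir}")

    patients = [read_patient_dir(p) for p in pdirs]

    # --- QC + exclusion ---------------------------------------------------
    qc_targets = {"wga_tumor": capture_a, "wga_normal": capture_a,
                  "unamplified_tumor": capture_b, "rna_tumor": coding}
    qc_rows: List[qc.SampleQC] = []
    filtered: Dict[str, Dict[str, Callset]] = {}
    for pt in patients:
        filtered[pt.patient_id] = {}
        for assay, cs in sorted(pt.callsets.items()):
            fc = qc.filter_calls(cs, thr)
            filtered[pt.patient_id][assay] = fc
            qc_rows.append(qc.compute_sample_qc(cs, pt.coverage[assay],
                                                qc_targets[assay], thr))
    dna_qc = [r for r in qc_rows if r.assay in DNA_ASSAYS]
    flagged = qc.flag_anomalous(dna_qc, thr)
    flagged_map = {(r.sample_id, r.assay): r for r in flagged}
    qc_rows = [flagged_map.get((r.sample_id, r.assay), r) for r in qc_rows]
    excluded_patients = sorted({r.sample_id for r in qc_rows if r.excluded})
    for pid in excluded_patients:
        reasons = [r.exclusion_reason for r in qc_rows
                   if r.sample_id == pid and r.excluded]
        logger.warning("patient %s excluded from comparisons: %s", pid, reasons)

    qc_df = pd.DataFrame([{
        "patient_id": r.sample_id, "assay": r.assay, "n_het": r.n_het,
        "n_hom": r.n_hom, "het_hom_ratio": r.het_hom_ratio,
        "ts_tv_ratio": r.ts_tv_ratio,
        "mean_target_coverage": r.mean_target_coverage,
        "excluded": r.excluded, "exclusion_reason": r.exclusion_reason,
    } for r in qc_rows])

    # --- cross-method comparisons (excluded patients drop out) ------------
    conc_rows, disc_rows = [], []
    partitions: Dict[str, conc.ConcordancePartition] = {}
    somatic_sets: Dict[str, som.SomaticCallset] = {}
    per_patient_frames: Dict[str, Dict[str, pd.DataFrame]] = {}
    for pt in patients:
        pid = pt.patient_id
        if pid in excluded_patients:
            continue
        f = filtered[pid]
        part = conc.partition(f["wga_tumor"], f["unamplified_tumor"], space)
        partitions[pid] = part
        n_wga_only, n_shared, n_unamp_only = part.counts
        pct_u = conc.partition_percentages(part, "union")
        pct_m = conc.partition_percentages(part, "method_specific")
        vaf_fit = conc.vaf_r2(conc.vaf_pairs(part))
        conc_rows.append({
            "patient_id": pid,
            "n_wga_only": n_wga_only, "n_shared": n_shared,
            "n_unamp_only": n_unamp_only,
            "pct_wga_only_union": pct_u[0], "pct_shared_union": pct_u[1],
            "pct_unamp_only_union": pct_u[2],
            "pct_wga_only_method": pct_m[0], "pct_shared_union2": pct_m[1],
            "pct_unamp_only_method": pct_m[2],
            "pct_wga_shared": conc.wga_shared_fraction(part),
            "vaf_r2": round_half_away(vaf_fit.r2, 3) if not math.isnan(vaf_fit.r2)
                      else math.nan,
        })

        cov_cls = conc.coverage_by_class(part, pt.coverage["wga_tumor"],
                                         pt.coverage["unamplified_tumor"])
        vaf_df = pd.DataFrame([{
            "chrom": p.key[0], "pos": p.key[1], "alt": p.key[2],
            "vaf_wga": p.vaf_wga, "vaf_unamp": p.vaf_unamp,
        } for p in conc.vaf_pairs(part)])
        part_df = pd.DataFrame(
            [{"chrom": k[0], "pos": k[1], "alt": k[2], "class": cls}
             for cls, keys in (("wga_only", part.wga_only), ("shared", part.shared),
                               ("unamp_only", part.unamp_only))
             for k in sorted(keys)])
        per_patient_frames[pid] = {"coverage_by_class": cov_cls,
                                   "vaf_pairs": vaf_df, "partition": part_df}

        res_wga = rescue_classify(part.wga_only.values(),
                                  pt.coverage["unamplified_tumor"],
                                  pt.evidence["unamplified_tumor"], thr)
        res_unamp = rescue_classify(part.unamp_only.values(),
                                    pt.coverage["wga_tumor"],
                                    pt.evidence["wga_tumor"], thr)
        interp = rescue_interpret(res_wga, res_unamp)

        tumor_restricted = conc.restrict(f["wga_tumor"], space)
        somatic_set = som.subtract_normal(tumor_restricted, f["wga_normal"],
                                          pt.coverage["wga_normal"], thr)
        somatic_sets[pid] = somatic_set
        unamp_restricted = conc.restrict(f["unamplified_tumor"], space)
        pct_confirmed = som.confirm_in_unamplified(somatic_set, unamp_restricted)
        mut_frac = som.mutation_fraction_by_class(part, somatic_set)

        row = {
            "patient_id": pid,
            "pct_unamp_unique_lowcov_in_wga": interp.pct_unamp_unique_low_cov_in_wga,
            "pct_wga_unique_lowcov_in_unamp": interp.pct_wga_unique_low_cov_in_unamp,
            "pct_wga_unique_unsupported": interp.false_positive_indicator,
            "n_tumor_specific": len(somatic_set),
            "pct_confirmed_in_unamplified": pct_confirmed,
            "pct_mut_wga_only": mut_frac["wga_only"],
            "pct_mut_shared": mut_frac["shared"],
            "pct_mut_unamp_only": mut_frac["unamp_only"],
            "pct_tumor_specific_rna_lowcov": math.nan,
            "pct_biallelic_of_expressed": math.nan,
            "pct_biallelic_with_dna_variant": math.nan,
        }
        if pt.has_rna:
            rna_cov = pt.coverage["rna_tumor"]
            row["pct_tumor_specific_rna_lowcov"] = rnaval.rna_coverage_check(
                somatic_set, rna_cov, thr)
            expressed = rnaval.expressed_genes(pt.expression, thr)
            biallelic = rnaval.biallelic_genes(f["rna_tumor"], expressed, genes,
                                               pt.expression, thr)
            if expressed:
                row["pct_biallelic_of_expressed"] = round_half_away(
                    100.0 * len(biallelic) / len(expressed), 1)
            row["pct_biallelic_with_dna_variant"] = rnaval.biallelic_dna_support(
                biallelic, tumor_restricted, unamp_restricted, genes)
        disc_rows.append(row)

    qc_digits = {"n_het": 0, "n_hom": 0, "het_hom_ratio": 2, "ts_tv_ratio": 2,
                 "mean_target_coverage": 2}
    conc_digits = {"n_wga_only": 0, "n_shared": 0, "n_unamp_only": 0,
                   "vaf_r2": 3}
    disc_digits = {"n_tumor_specific": 0}
    disc_digits.update({c: 1 for c in (
        "pct_unamp_unique_lowcov_in_wga", "pct_wga_unique_lowcov_in_unamp",
        "pct_wga_unique_unsupported", "pct_confirmed_in_unamplified",
        "pct_mut_wga_only", "pct_mut_shared", "pct_mut_unamp_only",
        "pct_tumor_specific_rna_lowcov", "pct_biallelic_of_expressed",
        "pct_biallelic_with_dna_variant")})

    qc_summary_parts = []
    for assay in ("wga_tumor", "unamplified_tumor", "wga_normal", "rna_tumor"):
        sub = qc_df[qc_df["assay"] == assay]
        if len(sub):
            block = _append_summary_rows(sub.reset_index(drop=True),
                                         "patient_id", qc_digits)
            block["assay"] = assay
            qc_summary_parts.append(block)
    qc_table = pd.concat(qc_summary_parts, ignore_index=True)

    conc_df = pd.DataFrame(conc_rows)
    disc_df = pd.DataFrame(disc_rows)
    conc_table = (_append_summary_rows(conc_df, "patient_id", conc_digits)
                  if len(conc_df) else conc_df)
    disc_table = (_append_summary_rows(disc_df, "patient_id", disc_digits)
                  if len(disc_df) else disc_df)

    report = CohortReport(qc_table=qc_table, concordance_table=conc_table,
                          discordance_table=disc_table,
                          excluded_patients=excluded_patients,
                          partitions=partitions, somatic_sets=somatic_sets)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header_note = ("# percentages: *_union columns use the union denominator; "
                       "*_method columns use unique/(unique+shared)\n")
        qc_table.to_csv(outdir / "qc_summary.tsv", sep="\t", index=False)
        with open(outdir / "concordance_summary.tsv", "w") as fh:
            fh.write(header_note)
            conc_table.to_csv(fh, sep="\t", index=False)
        disc_table.to_csv(outdir / "discordance_summary.tsv", sep="\t", index=False)
        for pid, frames in per_patient_frames.items():
            pdir = outdir / f"patient_{pid}"
            pdir.mkdir(exist_ok=True)
            for name, frame in frames.items():
                frame.to_csv(pdir / f"{name}.tsv", sep="\t", index=False)
    return report
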