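"""Readers and writers for the pipeline's plain-text interchange formats.

* β-matrix, detection-p and bead-count tables: tab-delimited, rows = CpGs,
  columns = samples, ``NA`` for missing;
* CpG coordinates and SNP metadata: tab-delimited keyed tables;
* genotypes: dosage TSV (rows = SNPs, columns = individuals) or a VCF with
  a ``DS`` FORMAT field (read via cyvcf2);
* sample sheet: CSV;
* ground truth and QC reports: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    BetaMatrix,
    DetectionStats,
    GenotypeTable,
    ProbeAnnotation,
    ReferenceProfiles,
    validate_sample_sheet,
)

__all__ = [
    "write_beta",
    "read_beta",
    "write_detection_stats",
    "read_detection_stats",
    "write_genotypes",
    "read_genotypes",
    "read_genotype_vcf",
    "write_reference",
    "read_reference",
    "read_probe_annotation",
    "write_cohort",
    "read_sample_sheet",
]


def _write_tsv(frame: pd.DataFrame, path, index_label: str) -> None:
    frame.to_csv(path, sep="\t", na_rep="NA", index_label=index_label)


def write_beta(beta: BetaMatrix, values_path, coords_path=None) -> None:
    _write_tsv(beta.values, values_path, "cpg_id")
    if coords_path is not None:
        _write_tsv(beta.coords, coords_path, "cpg_id")


def read_beta(values_path, coords_path) -> BetaMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0, na_values=["NA"])
    coords = pd.read_csv(coords_path, sep="\t", index_col=0, dtype={"chrom": str})
    return BetaMatrix(values, coords)


def write_detection_stats(stats: DetectionStats, detp_path, beads_path, zero_path) -> None:
    _write_tsv(stats.detection_p, detp_path, "cpg_id")
    _write_tsv(stats.bead_count, beads_path, "cpg_id")
    _write_tsv(stats.zero_intensity.astype(int), zero_path, "cpg_id")


def read_detection_stats(detp_path, beads_path, zero_path=None) -> DetectionStats:
    detp = pd.read_csv(detp_path, sep="\t", index_col=0)
    beads = pd.read_csv(beads_path, sep="\t", index_col=0)
    if zero_path is not None:
        zero = pd.read_csv(zero_path, sep="\t", index_col=0).astype(bool)
    else:
        zero = pd.DataFrame(False, index=detp.index, columns=detp.columns)
    return DetectionStats(detection_p=detp, bead_count=beads, zero_intensity=zero)


def write_genotypes(geno: GenotypeTable, dosage_path, meta_path) -> None:
    _write_tsv(geno.dosages, dosage_path, "snp_id")
    _write_tsv(geno.meta, meta_path, "snp_id")


def read_genotypes(dosage_path, meta_path) -> GenotypeTable:
    dosages = pd.read_csv(dosage_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype={"chrom": str})
    return GenotypeTable(dosages, meta)


def read_genotype_vcf(path, maf=None, hwe_p=None, mac=None, imp_r2=None) -> GenotypeTable:
    """Read a dosage VCF (FORMAT field ``DS``) into a `GenotypeTable`.

    Metadata fields are taken from the INFO column where present (keys
    ``MAF``, ``HWE``, ``MAC``, ``R2``); absent keys fall back to values
    computed from the dosages (MAF/MAC from rounded dosages, HWE by
    chi-square) so the downstream SNP filters always have inputs.
    """
    from cyvcf2 import VCF

    from .mqtl import _hwe_from_dosages

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta_rows, ids = [], [], []
    for var in vcf:
        ds = var.format("DS")
        if ds is None:
            raise ValueError(f"no DS field at {var.CHROM}:{var.POS}")
        dose = np.asarray(ds, dtype=float).reshape(-1)
        rows.append(dose)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        info = dict(var.INFO)
        meta_rows.append(
            {
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ref": var.REF,
                "alt": ",".join(var.ALT),
                "maf": info.get("MAF", np.nan),
                "hwe_p": info.get("HWE", np.nan),
                "mac": info.get("MAC", np.nan),
                "imp_r2": info.get("R2", np.nan),
            }
        )
    dosages = pd.DataFrame(rows, index=pd.Index(ids, name="snp_id"), columns=samples)
    meta = pd.DataFrame(meta_rows, index=dosages.index)
    hard = np.clip(np.round(dosages.to_numpy()), 0, 2)
    af = hard.mean(axis=1) / 2.0
    if meta["maf"].isna().any():
        meta.loc[meta["maf"].isna(), "maf"] = np.minimum(af, 1 - af)[meta["maf"].isna()]
    if meta["mac"].isna().any():
        macs = np.minimum(hard.sum(axis=1), 2 * len(samples) - hard.sum(axis=1))
        meta.loc[meta["mac"].isna(), "mac"] = macs[meta["mac"].isna()]
    if meta["hwe_p"].isna().any():
        hwe = _hwe_from_dosages(dosages.to_numpy())
        meta.loc[meta["hwe_p"].isna(), "hwe_p"] = hwe[meta["hwe_p"].isna()]
    if meta["imp_r2"].isna().any():
        meta.loc[meta["imp_r2"].isna(), "imp_r2"] = 1.0
    return GenotypeTable(dosages, meta)


def write_reference(reference: ReferenceProfiles, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_tsv(reference.stage1, outdir / "reference_stage1.tsv", "cpg_id")
    _write_tsv(reference.stage2, outdir / "reference_stage2.tsv", "cpg_id")
    (outdir / "signature1.txt").write_text("\n".join(reference.signature1) + "\n")
    (outdir / "signature2.txt").write_text("\n".join(reference.signature2) + "\n")


def read_reference(outdir) -> ReferenceProfiles:
    outdir = Path(outdir)
    stage1 = pd.read_csv(outdir / "reference_stage1.tsv", sep="\t", index_col=0)
    stage2 = pd.read_csv(outdir / "reference_stage2.tsv", sep="\t", index_col=0)
    sig1 = (outdir / "signature1.txt").read_text().split()
    sig2 = (outdir / "signature2.txt").read_text().split()
    return ReferenceProfiles(stage1, stage2, sig1, sig2)


def read_probe_annotation(path) -> ProbeAnnotation:
    flags = pd.read_csv(path, sep="\t", index_col=0).astype(bool)
    return ProbeAnnotation(flags)


def read_sample_sheet(path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path))


def write_cohort(cohort, outdir) -> None:
    """Write every artifact of a generated cohort to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_beta(cohort.beta, outdir / "beta.tsv", outdir / "cpg_coords.tsv")
    write_detection_stats(
        cohort.stats,
        outdir / "detection_p.tsv",
        outdir / "bead_count.tsv",
        outdir / "zero_intensity.tsv",
    )
    write_genotypes(cohort.genotypes, outdir / "dosages.tsv", outdir / "snp_meta.tsv")
    cohort.sheet.to_csv(outdir / "samples.csv", index=False)
    _write_tsv(cohort.annotation.flags.astype(int), outdir / "probe_annotation.tsv", "cpg_id")
    write_reference(cohort.reference, outdir / "reference")
    truth = {
        "true_fractions": {
            s: [float(v) for v in row]
            for s, row in cohort.truth.true_fractions.iterrows()
        },
        "celltypes": list(cohort.truth.true_fractions.columns),
        "mqtl_map": cohort.truth.mqtl_map.to_dict(orient="records"),
        "familial_component": {
            p: [float(v) for v in row]
            for p, row in cohort.truth.familial_component.iterrows()
        },
        "familial_cpgs": list(cohort.truth.familial_component.columns),
    }
    (outdir / "truth.json").write_text(json.dumps(truth))
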