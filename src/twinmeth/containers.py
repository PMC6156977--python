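"""Core in-memory containers shared across the pipeline.

All tabular data is held in pandas objects with explicit identifiers:

* methylation β-values as CpG × sample frames (``NaN`` = missing),
* genotype dosages as SNP × individual frames (values in [0, 2]),
* per-sample metadata in a flat "sample sheet" frame.

Containers validate their invariants on construction; operations never
mutate an input container in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns every sample sheet must carry.
SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "individual_id",
    "pair_id",
    "role",        # 1 or 2: twin ordering within the pair (arbitrary but fixed)
    "replicate",   # measurement index per individual, 1-based
    "age",
    "sex",         # "M" / "F"
    "platform",
)

#: Canonical cell-type labels for the two deconvolution stages.
STAGE1_CELLTYPES = ("Epi", "Fib", "IC")
IMMUNE_SUBTYPES = ("B", "NK", "CD4T", "CD8T", "Mono", "Neutro", "Eosino")
ALL_CELLTYPES = ("Epi", "Fib") + IMMUNE_SUBTYPES


class StructuralError(ValueError):
    """Shapes, identifiers or required columns do not line up."""


def _check_unique(index: pd.Index, what: str) -> None:
    if not index.is_unique:
        dup = index[index.duplicated()].tolist()[:5]
        raise StructuralError(f"duplicate {what}: {dup}")


@dataclass
class BetaMatrix:
    """CpG × sample methylation fractions with genomic coordinates.

    Parameters
    ----------
    values
        Frame indexed by CpG id with one column per sample id.  Entries are
        β-values in [0, 1]; ``NaN`` marks a missing (masked) measurement.
    coords
        Frame indexed by CpG id with columns ``chrom`` and ``pos``
        (1-based position of the interrogated cytosine).
    """

    values: pd.DataFrame
    coords: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "CpG ids")
        _check_unique(self.values.columns, "sample ids")
        vals = self.values.to_numpy(dtype=float)
        bad = np.isfinite(vals) & ((vals < 0) | (vals > 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"β outside [0,1] at ({self.values.index[i]}, "
                f"{self.values.columns[j]}): {vals[i, j]}"
            )
        if not {"chrom", "pos"}.issubset(self.coords.columns):
            raise StructuralError("coords needs 'chrom' and 'pos' columns")
        if not self.coords.index.equals(self.values.index):
            # allow superset annotation, but every CpG must be covered
            missing = self.values.index.difference(self.coords.index)
            if len(missing):
                raise StructuralError(
                    f"{len(missing)} CpGs lack coordinates, e.g. {missing[:3].tolist()}"
                )
            self.coords = self.coords.loc[self.values.index]

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_cpgs(self, cpg_ids) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[cpg_ids], self.coords.loc[cpg_ids])

    def copy(self) -> "BetaMatrix":
        return BetaMatrix(self.values.copy(), self.coords.copy())


@dataclass
class DetectionStats:
    """Per-(probe, sample) technical quality measures.

    ``detection_p`` is the probability the probe signal is background noise;
    ``bead_count`` the number of beads contributing to the measurement;
    ``zero_intensity`` flags probes with a raw intensity of exactly zero.
    """

    detection_p: pd.DataFrame
    bead_count: pd.DataFrame
    zero_intensity: pd.DataFrame

    def validate_against(self, beta: BetaMatrix) -> None:
        for name in ("detection_p", "bead_count", "zero_intensity"):
            frame = getattr(self, name)
            if not (
                frame.index.equals(beta.values.index)
                and frame.columns.equals(beta.values.columns)
            ):
                raise StructuralError(f"{name} is not aligned with the β-matrix")


@dataclass
class ProbeAnnotation:
    """Per-probe exclusion flags (one row per CpG).

    Columns: ``multi_mapping`` (probe aligns to multiple genomic locations),
    ``snp_overlap`` (a common SNP/INDEL overlaps the target CpG or extension
    base), ``autosomal``.
    """

    flags: pd.DataFrame

    REQUIRED = ("multi_mapping", "snp_overlap", "autosomal")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.flags.columns)
        if missing:
            raise StructuralError(f"probe annotation lacks columns {sorted(missing)}")
        _check_unique(self.flags.index, "annotated CpG ids")

    def validate_against(self, beta: BetaMatrix) -> None:
        missing = beta.values.index.difference(self.flags.index)
        if len(missing):
            raise StructuralError(
                f"{len(missing)} CpGs lack annotation, e.g. {missing[:3].tolist()}"
            )


@dataclass
class GenotypeTable:
    """SNP × individual allele dosages with per-SNP metadata.

    Dosages are expected reference-allele counts in [0, 2].  ``meta`` is
    indexed by SNP id with columns ``chrom``, ``pos`` (1-based), ``maf``,
    ``hwe_p``, ``mac`` and ``imp_r2``; allele columns (``ref``, ``alt``) are
    optional.
    """

    dosages: pd.DataFrame
    meta: pd.DataFrame

    META_REQUIRED = ("chrom", "pos", "maf", "hwe_p", "mac", "imp_r2")

    def __post_init__(self) -> None:
        _check_unique(self.dosages.index, "SNP ids")
        _check_unique(self.dosages.columns, "individual ids")
        vals = self.dosages.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=0.0) > 2:
            raise ValueError("dosages must lie in [0, 2]")
        missing = set(self.META_REQUIRED) - set(self.meta.columns)
        if missing:
            raise StructuralError(f"SNP metadata lacks columns {sorted(missing)}")
        if not self.meta.index.equals(self.dosages.index):
            raise StructuralError("SNP metadata index does not match dosage rows")
        if (self.meta["pos"] <= 0).any():
            raise ValueError("SNP positions must be strictly positive (1-based)")

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.index

    def subset_snps(self, snp_ids) -> "GenotypeTable":
        return GenotypeTable(self.dosages.loc[snp_ids], self.meta.loc[snp_ids])


@dataclass
class ReferenceProfiles:
    """Mean methylation profiles for the two deconvolution stages.

    ``stage1``: CpG × (Epi, Fib, IC) mean β; ``stage2``: CpG × 7 immune
    sub-types.  ``signature1``/``signature2`` list the CpGs on which the
    respective cell types are well separated and on which the robust fits
    are performed.
    """

    stage1: pd.DataFrame
    stage2: pd.DataFrame
    signature1: list = field(default_factory=list)
    signature2: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("stage1", "stage2"):
            frame = getattr(self, name)
            vals = frame.to_numpy(dtype=float)
            if (vals < 0).any() or (vals > 1).any():
                raise ValueError(f"{name} reference means must lie in [0, 1]")
        for sig, frame, name in (
            (self.signature1, self.stage1, "signature1"),
            (self.signature2, self.stage2, "signature2"),
        ):
            missing = pd.Index(sig).difference(frame.index)
            if len(missing):
                raise StructuralError(
                    f"{name} contains CpGs absent from the profiles: {missing[:3].tolist()}"
                )


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check required columns and identifier uniqueness of a sample sheet."""
    missing = set(SAMPLE_SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise StructuralError(f"sample sheet lacks columns {sorted(missing)}")
    _check_unique(pd.Index(sheet["sample_id"]), "sample ids")
    return sheet


def first_measurements(sheet: pd.DataFrame) -> pd.DataFrame:
    """One row per individual: the lowest replicate index of each."""
    sheet = sheet.sort_values(["individual_id", "replicate"], kind="stable")
    return sheet.drop_duplicates("individual_id", keep="first")


def complete_pairs(sheet: pd.DataFrame) -> pd.DataFrame:
    """Rows of `first_measurements` restricted to pairs with both co-twins."""
    first = first_measurements(sheet)
    counts = first.groupby("pair_id")["individual_id"].nunique()
    keep = counts[counts == 2].index
    return first[first["pair_id"].isin(keep)]


def twin_columns(sheet: pd.DataFrame):
    """Aligned (pair_ids, twin-1 sample ids, twin-2 sample ids).

    Uses one measurement per individual and the sample sheet's ``role``
    column for the twin-1/twin-2 assignment; incomplete pairs are dropped.
    """
    first = complete_pairs(sheet)
    t1 = first[first["role"] == 1].set_index("pair_id")["sample_id"]
    t2 = first[first["role"] == 2].set_index("pair_id")["sample_id"]
    pairs = t1.index.intersection(t2.index).sort_values()
    return list(pairs), t1.loc[pairs].tolist(), t2.loc[pairs].tolist()
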