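"""Probe- and sample-level quality control for array methylation data.

Cell-level rule: a (probe, sample) measurement is set to missing if its
raw intensity was exactly zero, its detection p-value exceeds 0.01, or
fewer than 3 beads contributed.  Probe-level rules: probes are dropped for
all samples if they map to multiple genomic locations, overlap a common
SNP/INDEL, have a success rate (fraction of non-missing samples) below
0.95, or are not autosomal.  Finally every sample's own success rate is
checked against the same 0.95 bound.

β-values are never altered — only masked or removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BetaMatrix, DetectionStats, ProbeAnnotation

__all__ = [
    "QCReport",
    "mask_failed_cells",
    "filter_probes",
    "sample_success_check",
    "run_qc",
]

#: Fixed attribution order for probe-drop rules: a probe is counted under
#: the first rule it violates (the retained set does not depend on this).
PROBE_RULES = ("multi_mapping", "snp_overlap", "low_success", "non_autosomal")


@dataclass
class QCReport:
    """Bookkeeping of what QC removed."""

    n_cells_set_missing: int
    n_probes_dropped_by_rule: dict = field(default_factory=dict)
    n_probes_retained: int = 0
    sample_success_rate: pd.Series | None = None

    @property
    def n_probes_dropped(self) -> int:
        return sum(self.n_probes_dropped_by_rule.values())

    def to_dict(self) -> dict:
        return {
            "n_cells_set_missing": int(self.n_cells_set_missing),
            "n_probes_dropped_by_rule": {
                k: int(v) for k, v in self.n_probes_dropped_by_rule.items()
            },
            "n_probes_retained": int(self.n_probes_retained),
            "sample_success_rate": (
                None
                if self.sample_success_rate is None
                else {k: float(v) for k, v in self.sample_success_rate.items()}
            ),
        }


def mask_failed_cells(
    beta: BetaMatrix,
    stats: DetectionStats,
    p_thresh: float = 0.01,
    min_beads: int = 3,
) -> tuple[BetaMatrix, int]:
    """Set failed (probe, sample) cells to missing.

    A cell fails if its intensity was exactly zero, detection p > ``p_thresh``
    (strict), or bead count < ``min_beads`` (strict).  Returns the masked
    matrix and the number of previously observed cells newly set missing.
    Idempotent: masking a masked matrix changes nothing.
    """
    stats.validate_against(beta)
    fail = (
        stats.zero_intensity.to_numpy(dtype=bool)
        | (stats.detection_p.to_numpy(dtype=float) > p_thresh)
        | (stats.bead_count.to_numpy(dtype=float) < min_beads)
    )
    vals = beta.values.to_numpy(dtype=float).copy()
    newly = int((fail & np.isfinite(vals)).sum())
    vals[fail] = np.nan
    masked = BetaMatrix(
        pd.DataFrame(vals, index=beta.values.index, columns=beta.values.columns),
        beta.coords,
    )
    return masked, newly


def _success_rates(values: pd.DataFrame, axis: int) -> pd.Series:
    return values.notna().mean(axis=axis)


def filter_probes(
    beta: BetaMatrix,
    annot: ProbeAnnotation,
    success_thresh: float = 0.95,
    n_cells_set_missing: int = 0,
) -> tuple[BetaMatrix, QCReport]:
    """Drop probes failing any probe-level rule; report per-rule counts.

    Rules (any one suffices to drop): multi-mapping probe, SNP/INDEL
    overlap, per-probe success rate < ``success_thresh`` across samples
    (strict, so a rate of exactly 0.95 is retained), non-autosomal.  The
    retained set is order-independent; the per-rule counts attribute each
    dropped probe to the first rule it violates in `PROBE_RULES` order.
    """
    annot.validate_against(beta)
    flags = annot.flags.loc[beta.values.index]
    rule_masks = {
        "multi_mapping": flags["multi_mapping"].to_numpy(dtype=bool),
        "snp_overlap": flags["snp_overlap"].to_numpy(dtype=bool),
        "low_success": (_success_rates(beta.values, axis=1) < success_thresh).to_numpy(),
        "non_autosomal": ~flags["autosomal"].to_numpy(dtype=bool),
    }
    drop = np.zeros(beta.n_cpgs, dtype=bool)
    counts = {}
    for rule in PROBE_RULES:
        hit = rule_masks[rule] & ~drop
        counts[rule] = int(hit.sum())
        drop |= rule_masks[rule]
    keep = beta.values.index[~drop]
    filtered = beta.subset_cpgs(keep)
    if filtered.n_cpgs == 0:
        warnings.warn("probe filtering removed every probe", stacklevel=2)
    report = QCReport(
        n_cells_set_missing=n_cells_set_missing,
        n_probes_dropped_by_rule=counts,
        n_probes_retained=int(len(keep)),
        sample_success_rate=_success_rates(filtered.values, axis=0)
        if filtered.n_cpgs
        else None,
    )
    return filtered, report


def sample_success_check(
    beta: BetaMatrix, success_thresh: float = 0.95
) -> pd.DataFrame:
    """Per-sample fraction of non-missing probes, with a pass/fail flag.

    A sample fails when its success rate is strictly below the threshold.
    """
    rate = _success_rates(beta.values, axis=0)
    return pd.DataFrame(
        {"success_rate": rate, "passed": rate >= success_thresh},
        index=beta.values.columns,
    )


def run_qc(
    beta: BetaMatrix,
    stats: DetectionStats,
    annot: ProbeAnnotation,
    p_thresh: float = 0.01,
    min_beads: int = 3,
    success_thresh: float = 0.95,
) -> tuple[BetaMatrix, QCReport, pd.DataFrame]:
    """Full QC: mask failed cells, filter probes, check samples."""
    masked, n_masked = mask_failed_cells(beta, stats, p_thresh, min_beads)
    filtered, report = filter_probes(
        masked, annot, success_thresh, n_cells_set_missing=n_masked
    )
    samples = sample_success_check(filtered, success_thresh)
    report.sample_success_rate = samples["success_rate"]
    return filtered, report, samples
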