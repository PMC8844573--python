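"""Reported Young's-modulus group means for iPSC-derived cardiac cells.

Measured untreated-control values (mean +- SEM, kPa) for cardiac progenitor
cells (CPC), immature cardiomyocytes (iCM, day 8) and more-differentiated
cardiomyocytes (mCM, day 30-32), obtained with two independent methods:
AFM colloidal-probe indentation of adherent cells and real-time
deformability cytometry (RT-DC) of the same cells in suspension. These
serve as reference inputs for cross-method comparison; they are
measurements, not outputs of this package.
"""
from __future__ import annotations

from .datatypes import GroupSummary

__all__ = ["AFM_GROUP_MEANS", "RTDC_GROUP_MEANS", "afm_summary", "rtdc_summary"]

# cell type -> (mean E in kPa, SEM in kPa)
AFM_GROUP_MEANS = {
    "CPC": (1.41, 0.11),
    "iCM": (1.03, 0.08),
    "mCM": (1.26, 0.10),
}

RTDC_GROUP_MEANS = {
    "CPC": (0.87, 0.02),
    "iCM": (0.95, 0.02),
    "mCM": (1.14, 0.02),
}


def _summary(table: dict, cell_type: str, method: str) -> GroupSummary:
    try:
        mean_kpa, sem_kpa = table[cell_type]
    except KeyError:
        raise KeyError(f"no reference value for cell type {cell_type!r}") from None
    # n of the underlying dataset is not part of the reference table
    return GroupSummary(
        group=f"{cell_type}/{method}", mean_E=mean_kpa * 1e3, sem_E=sem_kpa * 1e3, n=1
    )


def afm_summary(cell_type: str) -> GroupSummary:
    """Reference AFM group summary (E in Pa) for one cell type."""
    return _summary(AFM_GROUP_MEANS, cell_type, "AFM")


def rtdc_summary(cell_type: str) -> GroupSummary:
    """Reference RT-DC group summary (E in Pa) for one cell type."""
    return _summary(RTDC_GROUP_MEANS, cell_type, "RT-DC")
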