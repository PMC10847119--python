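"""Treg suppression-assay and peptide dose--response statistics.

The canonical suppression readout divides conventional T cells (Tconvs)
labelled with a proliferation dye between wells with and without regulatory
T cells (Tregs):

    % suppression = (prolif_alone - prolif_with_tregs) / prolif_alone * 100.

Negative values (proliferation enhancement) are reported as-is.  A second,
separately named variant scores suppression from the proliferation-dye MFI
itself (dye retention *rises* when division is suppressed):

    % suppression (MFI) = (mfi_with_tregs - mfi_baseline) / mfi_baseline * 100.

Dose--response experiments titrate peptide onto antigen-presenting cells and
read activation-marker MFI (e.g. CD69 on T cells, GARP on Tregs) in
replicate; :func:`dose_response_summary` reduces them to per-(marker,
concentration) means and SDs with log10 axis labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SuppressionCondition",
    "DoseResponsePoint",
    "percent_suppression",
    "percent_suppression_mfi",
    "potency_ratio",
    "dose_response_summary",
]


@dataclass(frozen=True)
class SuppressionCondition:
    """One Treg:Tconv co-culture condition with its proliferation readouts."""

    treg_to_tconv_ratio: str  # e.g. "1:1", "1:10", "1:100"
    proliferation_alone: float  # % of Tconvs proliferating without Tregs
    proliferation_with: float  # % proliferating with Tregs

    def __post_init__(self) -> None:
        for name in ("proliferation_alone", "proliferation_with"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percentage in [0, 100], got {v}")


@dataclass(frozen=True)
class DoseResponsePoint:
    """Replicate activation-marker MFI reads at one peptide concentration."""

    peptide_conc: float  # µg/mL; 0 allowed (no-peptide control)
    marker: str  # e.g. "CD69" or "GARP"
    mfi_values: tuple[float, ...]

    def __init__(self, peptide_conc: float, marker: str, mfi_values: Sequence[float]):
        if peptide_conc < 0:
            raise ValueError(f"peptide concentration must be >= 0, got {peptide_conc}")
        if len(mfi_values) < 1:
            raise ValueError("at least one replicate MFI value required")
        object.__setattr__(self, "peptide_conc", float(peptide_conc))
        object.__setattr__(self, "marker", marker)
        object.__setattr__(self, "mfi_values", tuple(float(v) for v in mfi_values))


def percent_suppression(cond: SuppressionCondition) -> float:
    """Suppression from proliferation percentages; may be negative."""
    if cond.proliferation_alone == 0:
        raise ValueError(
            "percent suppression is undefined when no Tconvs proliferate alone"
        )
    return (
        (cond.proliferation_alone - cond.proliferation_with)
        / cond.proliferation_alone
        * 100.0
    )


def percent_suppression_mfi(mfi_with: float, mfi_baseline: float) -> float:
    """Suppression as the % increase of proliferation-dye MFI over the
    no-Treg baseline (dye is retained when division is suppressed)."""
    if mfi_baseline <= 0:
        raise ValueError(f"baseline MFI must be > 0, got {mfi_baseline}")
    return (mfi_with - mfi_baseline) / mfi_baseline * 100.0


def potency_ratio(suppression_test: float, suppression_reference: float) -> float:
    """Fold-potency of a test condition over a reference condition."""
    if suppression_reference <= 0:
        raise ValueError(
            f"reference suppression must be > 0, got {suppression_reference}"
        )
    return suppression_test / suppression_reference


def dose_response_summary(points: Sequence[DoseResponsePoint]) -> pd.DataFrame:
    """Per-(marker, concentration) mean and SD of replicate MFI reads.

    Markers are never pooled.  The SD of a singleton is reported as 0 and
    flagged.  ``log10_conc`` carries the figure-style axis label
    (log10 µg/mL; -inf for the no-peptide control).

    Returns
    -------
    pandas.DataFrame
        Columns ``marker, peptide_conc, log10_conc, n, mean_mfi, sd_mfi,
        singleton``, sorted by marker then concentration.
    """
    if not points:
        raise ValueError("no dose-response points supplied")
    # pool replicates of points sharing (marker, concentration)
    long = pd.DataFrame(
        [
            {"marker": p.marker, "peptide_conc": p.peptide_conc, "mfi": v}
            for p in points
            for v in p.mfi_values
        ]
    )
    rows = []
    for (marker, conc), grp in long.groupby(["marker", "peptide_conc"], sort=True):
        vals = grp["mfi"].to_numpy()
        rows.append(
            {
                "marker": marker,
                "peptide_conc": conc,
                "log10_conc": math.log10(conc) if conc > 0 else -math.inf,
                "n": vals.size,
                "mean_mfi": float(vals.mean()),
                "sd_mfi": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "singleton": vals.size == 1,
            }
        )
    return pd.DataFrame(rows)
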