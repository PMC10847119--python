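"""Half-life--weighted epitope stability scoring from two-timepoint binding reads.

MHC-II binding screens report a peptide--HLA binding signal as a percentage
of a positive-control epitope's signal ("Reveal score"), read at 0 h and at a
later timepoint (24 h by default).  Assuming one-phase exponential
dissociation ``Y = Y0 * exp(-k * t)``, the decay rate is

    k = -ln(y_t / y_0) / t,        t_half = ln(2) / k,

and candidate epitopes are ranked by the Stability Index

    SI = t_half * y_0 / 100,

which weights the half-life by the initial binding strength so that weakly
binding but slowly decaying peptides are not over-represented.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "RevealMeasurement",
    "StabilityResult",
    "stability_score",
    "rank_peptides",
    "DEFAULT_T_HALF_CAP",
]

#: Default half-life assigned to non-decaying peptides (k <= 0): four times
#: the 24 h assay horizon.  A finite cap keeps the ranking total.
DEFAULT_T_HALF_CAP = 96.0


@dataclass(frozen=True)
class RevealMeasurement:
    """Two-timepoint peptide--HLA binding scores (% of positive control).

    Scores are percentages relative to a positive-control epitope and may
    exceed 100.
    """

    peptide_name: str
    y0: float
    y24: float
    t: float = 24.0

    def __post_init__(self) -> None:
        if self.y0 < 0 or self.y24 < 0:
            raise ValueError(
                f"{self.peptide_name}: binding scores must be >= 0, "
                f"got y0={self.y0}, y24={self.y24}"
            )
        if self.t <= 0:
            raise ValueError(f"{self.peptide_name}: elapsed time must be > 0, got {self.t}")


@dataclass(frozen=True)
class StabilityResult:
    peptide_name: str
    k: float  # decay rate constant, per hour
    t_half: float  # hours
    stability_index: float
    capped: bool  # True when the input did not decay and t_half was capped


def stability_score(
    m: RevealMeasurement, t_half_cap: float = DEFAULT_T_HALF_CAP
) -> StabilityResult:
    """Score one peptide's stability from its two-timepoint binding reads.

    Degenerate inputs are mapped to defined outputs rather than errors:

    * ``y24 >= y0`` (no apparent decay, k <= 0): the half-life is set to
      ``t_half_cap`` and the result is flagged ``capped``.  Assay noise can
      inflate the late read, so this is not treated as an error.
    * ``y24 == 0`` (signal fully lost): t_half = 0, SI = 0.
    * ``y0 == 0`` (never bound): all outputs 0, not capped.
    """
    if m.y0 == 0:
        return StabilityResult(m.peptide_name, k=0.0, t_half=0.0, stability_index=0.0, capped=False)
    if m.y24 == 0:
        return StabilityResult(
            m.peptide_name, k=math.inf, t_half=0.0, stability_index=0.0, capped=False
        )
    k = -math.log(m.y24 / m.y0) / m.t
    if k <= 0:
        t_half = t_half_cap
        capped = True
        k = max(k, 0.0)
    else:
        # the cap also binds on near-zero decay, so the score is monotone
        # in the late read across the no-decay boundary
        t_half = min(math.log(2) / k, t_half_cap)
        capped = t_half == t_half_cap
    return StabilityResult(
        peptide_name=m.peptide_name,
        k=k,
        t_half=t_half,
        stability_index=t_half * m.y0 / 100.0,
        capped=capped,
    )


def rank_peptides(
    measurements: Sequence[RevealMeasurement] | Iterable[RevealMeasurement],
    top_n: int = 5,
    t_half_cap: float = DEFAULT_T_HALF_CAP,
) -> pd.DataFrame:
    """Score and rank peptides by descending Stability Index.

    Ties are broken by higher ``y0``, then alphabetically by name.  The top
    ``top_n`` rows are flagged ``selected``.

    Returns
    -------
    pandas.DataFrame
        Columns ``peptide_name, y0, y24, k, t_half, stability_index,
        capped, rank, selected``, ordered by rank.
    """
    measurements = list(measurements)
    if not measurements:
        raise ValueError("no measurements to rank")
    names = [m.peptide_name for m in measurements]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate peptide names: {sorted(dupes)}")
    if top_n > len(measurements):
        warnings.warn(
            f"top_n={top_n} exceeds the number of peptides ({len(measurements)}); "
            "selecting all",
            stacklevel=2,
        )
    rows = []
    for m in measurements:
        r = stability_score(m, t_half_cap=t_half_cap)
        rows.append(
            {
                "peptide_name": m.peptide_name,
                "y0": m.y0,
                "y24": m.y24,
                "k": r.k,
                "t_half": r.t_half,
                "stability_index": r.stability_index,
                "capped": r.capped,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["stability_index", "y0", "peptide_name"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = df.index + 1
    df["selected"] = df["rank"] <= top_n
    return df
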