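"""Semi-quantitative renal-injury scoring and ordinal proteinuria mapping.

Lupus-nephritis models are scored on periodic acid--Schiff (PAS) stained
kidney sections using per-glomerulus and per-high-powered-field (hpf)
rules:

* glomerular segmental necrosis: >= 50% of the glomerulus occupied by
  PAS-positive material;
* glomerular crescent: two or more layers of cells in Bowman's space;
* mesangial proliferation: three or more nuclei clumped together;
* hypercellularity: nuclei per glomerular cross-section (gcs), averaged
  over at least 20 consecutive equatorial glomeruli;
* tubulointerstitial injury: a field scores 1 if it shows any of
  infiltrates, tubular dilation, necrosis or protein casts (>= 20 hpf).

Dipstick proteinuria is mapped to the ordinal 0--4 scale anchored at
0 (negative/trace), 1 (0.30 g/L), 2 (1 g/L), 3 (3 g/L), 4 (>= 20 g/L);
numeric readings are binned into half-open intervals with inclusive lower
edges so each printed anchor maps to its own score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GlomerulusObservation",
    "HpfObservation",
    "GlomerulusFlags",
    "KidneySummary",
    "score_glomerulus",
    "summarize_kidney",
    "summarize_groups",
    "proteinuria_score",
    "MIN_GLOMERULI",
    "MIN_HPF",
]

#: Minimum recommended sampling per kidney; shortfalls are QC-flagged.
MIN_GLOMERULI = 20
MIN_HPF = 20

# Proteinuria bin lower edges (g/L) and their ordinal scores.
_PROTEINURIA_EDGES = [(20.0, 4), (3.0, 3), (1.0, 2), (0.30, 1), (0.0, 0)]


@dataclass(frozen=True)
class GlomerulusObservation:
    """Raw per-glomerulus measurements from a PAS-stained section."""

    kidney_id: str
    pas_positive_fraction: float  # fraction of the tuft occupied, [0, 1]
    cell_count: int  # nuclei per glomerular cross-section
    max_clumped_nuclei: int = 0  # largest mesangial nucleus clump
    bowman_cell_layers: int = 1  # cell layers in Bowman's space

    def __post_init__(self) -> None:
        if not 0 <= self.pas_positive_fraction <= 1:
            raise ValueError(
                f"pas_positive_fraction must be in [0, 1], got {self.pas_positive_fraction}"
            )
        for name in ("cell_count", "max_clumped_nuclei", "bowman_cell_layers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class HpfObservation:
    """Binary tubulointerstitial findings in one high-powered field."""

    kidney_id: str
    infiltrate: bool = False
    tubular_dilation: bool = False
    necrosis: bool = False
    protein_casts: bool = False

    @property
    def any_injury(self) -> bool:
        return self.infiltrate or self.tubular_dilation or self.necrosis or self.protein_casts


@dataclass(frozen=True)
class GlomerulusFlags:
    necrotic: bool
    crescent: bool
    mesangial_proliferative: bool


@dataclass(frozen=True)
class KidneySummary:
    kidney_id: str
    pct_necrotic_glomeruli: float
    mean_cells_per_gcs: float
    pct_mesangial_proliferation: float
    pct_crescents: float
    tubulointerstitial_pct: float  # % of hpf scoring 1
    n_glomeruli: int
    n_hpf: int
    qc_flags: tuple[str, ...] = field(default_factory=tuple)


def score_glomerulus(obs: GlomerulusObservation) -> GlomerulusFlags:
    """Apply the per-glomerulus scoring rules (all thresholds inclusive)."""
    return GlomerulusFlags(
        necrotic=obs.pas_positive_fraction >= 0.5,
        crescent=obs.bowman_cell_layers >= 2,
        mesangial_proliferative=obs.max_clumped_nuclei >= 3,
    )


def summarize_kidney(
    glomeruli: Sequence[GlomerulusObservation],
    hpfs: Sequence[HpfObservation],
) -> KidneySummary:
    """Composite per-kidney injury scores.

    Short samples (< 20 glomeruli or < 20 hpf) are QC-flagged, not
    rejected; empty inputs are an error.
    """
    if not glomeruli or not hpfs:
        raise ValueError("at least one glomerulus and one hpf observation required")
    kidney_ids = {o.kidney_id for o in glomeruli} | {o.kidney_id for o in hpfs}
    if len(kidney_ids) != 1:
        raise ValueError(f"observations span multiple kidneys: {sorted(kidney_ids)}")
    (kidney_id,) = kidney_ids

    flags = [score_glomerulus(o) for o in glomeruli]
    n_g = len(glomeruli)
    n_h = len(hpfs)
    qc = []
    if n_g < MIN_GLOMERULI:
        qc.append(f"only {n_g} glomeruli (< {MIN_GLOMERULI})")
    if n_h < MIN_HPF:
        qc.append(f"only {n_h} hpf (< {MIN_HPF})")
    return KidneySummary(
        kidney_id=kidney_id,
        pct_necrotic_glomeruli=100.0 * sum(f.necrotic for f in flags) / n_g,
        mean_cells_per_gcs=float(np.mean([o.cell_count for o in glomeruli])),
        pct_mesangial_proliferation=100.0
        * sum(f.mesangial_proliferative for f in flags)
        / n_g,
        pct_crescents=100.0 * sum(f.crescent for f in flags) / n_g,
        tubulointerstitial_pct=100.0 * sum(o.any_injury for o in hpfs) / n_h,
        n_glomeruli=n_g,
        n_hpf=n_h,
        qc_flags=tuple(qc),
    )


def summarize_groups(
    summaries: Sequence[KidneySummary], groups: dict[str, str]
) -> pd.DataFrame:
    """Mean of each per-kidney score within treatment groups.

    ``groups`` maps kidney_id -> group label.  Returns one row per group
    with the group means of every score plus the number of kidneys.
    """
    if not summaries:
        raise ValueError("no kidney summaries supplied")
    missing = [s.kidney_id for s in summaries if s.kidney_id not in groups]
    if missing:
        raise ValueError(f"kidneys without a group label: {missing}")
    df = pd.DataFrame(
        [
            {
                "kidney_id": s.kidney_id,
                "group": groups[s.kidney_id],
                "pct_necrotic_glomeruli": s.pct_necrotic_glomeruli,
                "mean_cells_per_gcs": s.mean_cells_per_gcs,
                "pct_mesangial_proliferation": s.pct_mesangial_proliferation,
                "pct_crescents": s.pct_crescents,
                "tubulointerstitial_pct": s.tubulointerstitial_pct,
            }
            for s in summaries
        ]
    )
    out = (
        df.groupby("group", as_index=False)
        .agg(
            n_kidneys=("kidney_id", "size"),
            pct_necrotic_glomeruli=("pct_necrotic_glomeruli", "mean"),
            mean_cells_per_gcs=("mean_cells_per_gcs", "mean"),
            pct_mesangial_proliferation=("pct_mesangial_proliferation", "mean"),
            pct_crescents=("pct_crescents", "mean"),
            tubulointerstitial_pct=("tubulointerstitial_pct", "mean"),
        )
        .sort_values("group", kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def proteinuria_score(reading: str | float) -> int:
    """Map a dipstick reading to the ordinal 0--4 proteinuria score.

    ``reading`` is either the categorical label ``"negative"``/``"trace"``
    or a non-negative numeric value in g/L.  Numeric bins are
    [0, 0.30) -> 0, [0.30, 1) -> 1, [1, 3) -> 2, [3, 20) -> 3,
    [20, inf) -> 4.
    """
    if isinstance(reading, str):
        label = reading.strip().lower()
        if label in {"negative", "neg", "trace"}:
            return 0
        try:
            reading = float(label)
        except ValueError:
            raise ValueError(f"unrecognised dipstick reading {reading!r}") from None
    value = float(reading)
    if value < 0:
        raise ValueError(f"proteinuria reading must be >= 0 g/L, got {value}")
    for edge, score in _PROTEINURIA_EDGES:
        if value >= edge:
            return score
    raise AssertionError("unreachable")
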