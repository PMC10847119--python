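"""Apparent-affinity estimation from dextramer saturation-binding titrations.

Peptide--HLA dextramer reagents are titrated onto TCR-transduced cells (the
standard design is seven twofold serial dilutions from 5 nM plus a 0 nM
well) and the bound signal is read as mean fluorescence intensity (MFI).
Under one-site equilibrium binding,

    bound(c) = Bmax * c / (KD + c),

the Scatchard transform ``bound/free`` versus ``bound`` is linear with slope
``-1/KD`` and x-intercept ``Bmax``; the apparent dissociation constant is the
negative reciprocal of the slope of the ordinary least-squares line, and
``Bmax = -intercept/slope``.  Free ligand is approximated by the nominal
staining concentration (no depletion correction), and the 0 nM well, when
present, is used as background and subtracted from every point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TitrationSeries",
    "ScatchardFit",
    "dilution_series",
    "one_site_bound",
    "fit_scatchard",
]


@dataclass(frozen=True)
class TitrationSeries:
    """A ligand titration: concentrations (nM) and bound-signal MFI values.

    At most one zero concentration is allowed; its MFI is treated as
    background by :func:`fit_scatchard`.
    """

    label: str
    concentrations: tuple[float, ...]
    mfi: tuple[float, ...]

    def __init__(self, label: str, concentrations: Sequence[float], mfi: Sequence[float]):
        if len(concentrations) != len(mfi):
            raise ValueError(
                f"{label}: {len(concentrations)} concentrations but {len(mfi)} MFI values"
            )
        conc = np.asarray(concentrations, dtype=float)
        if np.any(conc < 0):
            raise ValueError(f"{label}: concentrations must be non-negative")
        if np.sum(conc == 0) > 1:
            raise ValueError(f"{label}: at most one zero concentration allowed")
        if len(np.unique(conc)) != len(conc):
            raise ValueError(f"{label}: duplicate concentrations")
        order = np.argsort(conc)
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "concentrations", tuple(conc[order]))
        object.__setattr__(self, "mfi", tuple(np.asarray(mfi, dtype=float)[order]))

    @property
    def background(self) -> float | None:
        """MFI at the 0 nM point, or None if no zero-concentration well."""
        if self.concentrations and self.concentrations[0] == 0.0:
            return self.mfi[0]
        return None


@dataclass(frozen=True)
class ScatchardFit:
    """Result of a Scatchard linearisation fit.

    ``kd`` and ``bmax`` are None when the slope is non-negative (flagged
    ``non_binding``): a non-decreasing bound/free vs bound line carries no
    one-site affinity information.
    """

    label: str
    slope: float  # (MFI/nM) per MFI
    intercept: float  # MFI/nM
    kd: float | None  # nM
    bmax: float | None  # MFI
    r2: float
    n_points: int
    non_binding: bool
    background_subtracted: bool


def dilution_series(
    start: float, n_dilutions: int = 7, factor: float = 2.0, include_zero: bool = True
) -> list[float]:
    """Concentrations of a serial dilution, sorted ascending.

    Returns ``{start / factor**i : i = 0..n_dilutions-1}``, plus 0 when
    ``include_zero``.  The default arguments give the standard 8-point
    dextramer design: seven twofold dilutions from ``start`` plus a 0 nM
    background well.
    """
    if start <= 0:
        raise ValueError(f"starting concentration must be > 0, got {start}")
    if n_dilutions < 1:
        raise ValueError(f"n_dilutions must be >= 1, got {n_dilutions}")
    if factor <= 1:
        raise ValueError(f"dilution factor must be > 1, got {factor}")
    conc = [start / factor**i for i in range(n_dilutions)]
    if include_zero:
        conc.append(0.0)
    return sorted(conc)


def one_site_bound(c, kd: float, bmax: float):
    """One-site equilibrium binding: ``bmax * c / (kd + c)``.

    Accepts scalar or array concentrations (nM); returns the same shape.
    """
    if kd <= 0:
        raise ValueError(f"kd must be > 0, got {kd}")
    if bmax < 0:
        raise ValueError(f"bmax must be >= 0, got {bmax}")
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("concentrations must be >= 0")
    out = bmax * c_arr / (kd + c_arr)
    return out if c_arr.ndim else float(out)


def fit_scatchard(series: TitrationSeries) -> ScatchardFit:
    """Estimate apparent KD and Bmax by Scatchard linearisation.

    If the series has a 0 nM well its MFI is subtracted from all points as
    background; the 0 nM point itself is excluded from the fit.  Points
    whose background-subtracted bound signal is <= 0 are dropped with a
    warning.  Ordinary least squares of bound/free on bound gives
    ``kd = -1/slope`` and ``bmax = -intercept/slope``; a slope >= 0 yields
    no affinity estimate and the ``non_binding`` flag.

    Raises
    ------
    ValueError
        If fewer than 3 usable points remain.
    """
    conc = np.asarray(series.concentrations, dtype=float)
    mfi = np.asarray(series.mfi, dtype=float)
    background = series.background
    if background is not None:
        bound = mfi - background
        nonzero = conc > 0
        conc, bound = conc[nonzero], bound[nonzero]
        background_subtracted = True
    else:
        bound = mfi.copy()
        background_subtracted = False

    usable = bound > 0
    if not np.all(usable):
        warnings.warn(
            f"{series.label}: dropping {int((~usable).sum())} point(s) with "
            "non-positive bound signal after background subtraction",
            stacklevel=2,
        )
        conc, bound = conc[usable], bound[usable]
    if len(conc) < 3:
        raise ValueError(
            f"{series.label}: only {len(conc)} usable point(s); at least 3 "
            "nonzero concentrations with positive bound signal are required"
        )

    # free ligand approximated by the nominal total concentration
    ratio = bound / conc
    if np.allclose(ratio, ratio[0], rtol=0.0, atol=0.0) or np.ptp(bound) == 0:
        # perfectly flat inputs: degenerate regression, report zero slope
        slope, intercept, r2 = 0.0, float(np.mean(ratio)), 0.0
    else:
        res = stats.linregress(bound, ratio)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)

    if slope >= 0:
        return ScatchardFit(
            label=series.label,
            slope=slope,
            intercept=intercept,
            kd=None,
            bmax=None,
            r2=r2,
            n_points=len(conc),
            non_binding=True,
            background_subtracted=background_subtracted,
        )
    return ScatchardFit(
        label=series.label,
        slope=slope,
        intercept=intercept,
        kd=-1.0 / slope,
        bmax=-intercept / slope,
        r2=r2,
        n_points=len(conc),
        non_binding=False,
        background_subtracted=background_subtracted,
    )
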