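"""Ratiometric roGFP2 probe math.

The Grx1-roGFP2 sensor reports the glutathione redox potential through two
excitation maxima (405 and 488 nm) whose relative intensity flips with the
disulfide state of the fluorophore.  The degree of probe oxidation (OxD) maps
the per-event 405/488 signal onto a 0 (fully reduced) .. 1 (fully oxidized)
scale using endpoint measurements from chemically clamped control populations
(DTT-reduced, diamide-oxidized).

Two equivalent forms are provided:

* the six-intensity form, anchored on the control-population channel
  intensities (I405red, I488red, I405ox, I488ox);
* the wavelength-ratio form, anchored on the two endpoint ratios
  (Rred = I405red/I488red, Rox = I405ox/I488ox).

For imaged cells the same normalization is applied to area-mean intensities;
the result is called OxD* to distinguish it from cytometry-derived OxD.

OxD values are *not* clipped to [0, 1] by default: per-cell normalization
against population-average endpoints can legitimately produce values outside
the nominal scale (e.g. 150% oxidation for bright outliers), and clipping
would hide that behavior.  Pass ``clip=True`` to restrict the output.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationModel",
    "ImagingCalibration",
    "CalibrationError",
    "CalibrationInversionError",
    "oxd_from_ratio",
    "oxd_from_intensities",
    "oxd_star",
    "oxd_star_single_channel",
    "fit_calibration",
    "zero_intercept_slope",
]

class CalibrationError(ValueError):
    """Invalid or inconsistent calibration inputs."""


class CalibrationInversionError(CalibrationError):
    """Oxidized-control ratio does not exceed the reduced-control ratio.

    Almost always means the two control populations were swapped.
    """


@dataclass(frozen=True)
class CalibrationModel:
    """Endpoint statistics of the fully reduced / fully oxidized controls.

    The six intensity anchors are stored alongside the two endpoint ratios
    ``r_red`` / ``r_ox`` (the zero-intercept slopes of the 405-vs-488 linear
    fits) so that the six-intensity and ratio forms of the OxD computation are
    mutually consistent: ``r_red == i405_red_mean / i488_red_mean`` and
    likewise for the oxidized anchors, exactly.

    Parameters
    ----------
    i405_red_mean, i488_red_mean, i405_ox_mean, i488_ox_mean
        Control-population intensity anchors (arbitrary units, > 0).
    r_red, r_ox
        Endpoint 405/488 ratios; ``r_ox > r_red > 0``.
    r2_red, r2_ox
        Coefficients of determination of the control fits, in [0, 1].
    n_red, n_ox
        Number of control events behind each fit.
    source_time
        Culture age (hours) at which the controls were measured; all later
        time points are normalized against these anchors.
    """

    i405_red_mean: float
    i488_red_mean: float
    i405_ox_mean: float
    i488_ox_mean: float
    r_red: float
    r_ox: float
    r2_red: float = 1.0
    r2_ox: float = 1.0
    n_red: int = 0
    n_ox: int = 0
    source_time: float = 24.0

    def __post_init__(self) -> None:
        if not (self.r_red > 0.0 and self.r_ox > self.r_red):
            raise CalibrationInversionError(
                f"require r_ox > r_red > 0, got r_red={self.r_red!r}, "
                f"r_ox={self.r_ox!r} (controls possibly swapped)"
            )
        for name in ("i405_red_mean", "i488_red_mean", "i405_ox_mean", "i488_ox_mean"):
            if not getattr(self, name) > 0.0:
                raise CalibrationError(f"{name} must be > 0")
        for name in ("r2_red", "r2_ox"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise CalibrationError(f"{name} must lie in [0, 1], got {v!r}")
        if not math.isclose(self.r_red, self.i405_red_mean / self.i488_red_mean, rel_tol=1e-6):
            raise CalibrationError("r_red inconsistent with reduced intensity anchors")
        if not math.isclose(self.r_ox, self.i405_ox_mean / self.i488_ox_mean, rel_tol=1e-6):
            raise CalibrationError("r_ox inconsistent with oxidized intensity anchors")

    # -- serialization ---------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write the calibration as a flat key/value TSV."""
        items = asdict(self)
        with open(path, "w") as fh:
            for key, value in items.items():
                fh.write(f"{key}\t{value!r}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CalibrationModel":
        """Read a calibration previously written by :meth:`to_tsv`."""
        kwargs: dict[str, float | int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("\t")
                kwargs[key] = int(value) if key in ("n_red", "n_ox") else float(value)
        return cls(**kwargs)  # type: ignore[arg-type]


@dataclass(frozen=True)
class ImagingCalibration:
    """Endpoint ratios for microscopy-derived OxD*.

    Imaged cells are normalized by surface area rather than total
    fluorescence; the endpoints here are the area-mean 405/488 ratios of fully
    reduced and fully oxidized reference cells.
    """

    r_red_img: float
    r_ox_img: float

    def __post_init__(self) -> None:
        if not (self.r_red_img > 0.0 and self.r_ox_img > self.r_red_img):
            raise CalibrationInversionError(
                f"require r_ox_img > r_red_img > 0, got "
                f"r_red_img={self.r_red_img!r}, r_ox_img={self.r_ox_img!r}"
            )


def oxd_from_ratio(r, cal: CalibrationModel, *, clip: bool = False):
    """Degree of oxidation from per-event 405/488 ratios.

    Implements ``OxD = (R - Rred) / ((Rox - R) + (R - Rred))``.  The
    two-term denominator equals ``Rox - Rred`` whenever it is evaluated, so
    the map is affine in R with OxD(Rred) = 0 and OxD(Rox) = 1.

    Parameters
    ----------
    r
        Scalar or array of 405/488 ratios (> 0).
    cal
        Fitted endpoints.
    clip
        If True, clip the result to [0, 1].

    Returns
    -------
    Scalar or array of OxD values.  Events with a nonpositive denominator are
    flagged as NaN (undefined OxD) rather than raising.
    """
    r = np.asarray(r, dtype=float)
    denom = (cal.r_ox - r) + (r - cal.r_red)
    with np.errstate(divide="ignore", invalid="ignore"):
        oxd = np.where(denom > 0.0, (r - cal.r_red) / denom, np.nan)
    if clip:
        oxd = np.clip(oxd, 0.0, 1.0)
    return float(oxd) if oxd.ndim == 0 else oxd


def oxd_from_intensities(i405, i488, cal: CalibrationModel, *, clip: bool = False):
    """Degree of oxidation directly from the six measured intensities.

    OxD = (I405*I488red - I405red*I488) /
          (I405*I488red - I405*I488ox + I405ox*I488 - I405red*I488)

    where the control anchors come from ``cal``.  When the two 488 anchors
    coincide this reduces algebraically to :func:`oxd_from_ratio`.

    Events with a zero or negative denominator are returned as NaN
    (undefined OxD), not raised.
    """
    i405 = np.asarray(i405, dtype=float)
    i488 = np.asarray(i488, dtype=float)
    num = i405 * cal.i488_red_mean - cal.i405_red_mean * i488
    denom = (
        i405 * cal.i488_red_mean
        - i405 * cal.i488_ox_mean
        + cal.i405_ox_mean * i488
        - cal.i405_red_mean * i488
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        oxd = np.where(denom > 0.0, num / denom, np.nan)
    if clip:
        oxd = np.clip(oxd, 0.0, 1.0)
    return float(oxd) if oxd.ndim == 0 else oxd


def oxd_star(mean_i405_cell, mean_i488_cell, img_cal: ImagingCalibration, *, clip: bool = False):
    """Per-cell OxD* from area-mean 405 and 488 intensities.

    The per-cell ratio ``Rbar = mean_i405 / mean_i488`` is mapped linearly
    onto the imaging endpoints: ``(Rbar - Rred) / (Rox - Rred)``.  Using the
    ratio of area means keeps the result independent of probe expression
    level.  Unclipped by default; individual cells can exceed the [0, 1]
    scale.
    """
    rbar = np.asarray(mean_i405_cell, dtype=float) / np.asarray(mean_i488_cell, dtype=float)
    span = img_cal.r_ox_img - img_cal.r_red_img
    oxd = (rbar - img_cal.r_red_img) / span
    if clip:
        oxd = np.clip(oxd, 0.0, 1.0)
    return float(oxd) if oxd.ndim == 0 else oxd


def oxd_star_single_channel(i_mean, i_red: float, i_ox: float, *, clip: bool = False):
    """Literal single-channel OxD*: ``(Imean - Ired) / (Iox - Ired)``.

    Provided for fidelity with instruments that report a single area-mean
    intensity; the ratiometric :func:`oxd_star` is the recommended mode.
    """
    if i_ox == i_red:
        raise CalibrationError("i_ox and i_red endpoints must differ")
    oxd = (np.asarray(i_mean, dtype=float) - i_red) / (i_ox - i_red)
    if clip:
        oxd = np.clip(oxd, 0.0, 1.0)
    return float(oxd) if oxd.ndim == 0 else oxd


def zero_intercept_slope(i488: np.ndarray, i405: np.ndarray) -> tuple[float, float]:
    """Zero-intercept least-squares fit of i405 = s * i488.

    Returns ``(slope, r2)`` where ``slope = sum(x*y) / sum(x**2)`` and the
    coefficient of determination is computed against the mean of i405
    (1 - SSres/SStot), so a through-origin fit of uncorrelated data scores
    near zero rather than spuriously high.
    """
    x = np.asarray(i488, dtype=float)
    y = np.asarray(i405, dtype=float)
    sxx = float(np.sum(x * x))
    if sxx <= 0.0:
        raise CalibrationError("cannot fit: sum of squared 488 intensities is zero")
    slope = float(np.sum(x * y)) / sxx
    resid = y - slope * x
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sstot if sstot > 0 else 1.0
    return slope, max(0.0, min(1.0, r2))


def fit_calibration(
    reduced_events: pd.DataFrame,
    oxidized_events: pd.DataFrame,
    *,
    min_events: int = 50,
    source_time: float = 24.0,
    free_intercept: bool = False,
) -> CalibrationModel:
    """Fit endpoint ratios from fully reduced / fully oxidized control events.

    Each control population is fit with a zero-intercept least-squares line
    i405 = s * i488 on the linear intensity scale; the slope becomes the
    endpoint ratio.  The 488 intensity anchor is the control-population
    channel mean and the 405 anchor is the fitted line evaluated there
    (slope x mean488), which keeps the slope and anchor ratio identical.

    Parameters
    ----------
    reduced_events, oxidized_events
        Event tables with ``i405`` and ``i488`` columns; expected to be
        already live-gated and probe-positive.
    min_events
        Minimum events required per control.
    free_intercept
        If True, fit an ordinary (intercept-bearing) line and use its slope;
        anchors are still taken at the mean 488 intensity.

    Raises
    ------
    CalibrationError
        Too few events in either control.
    CalibrationInversionError
        Fitted oxidized slope does not exceed the reduced slope.
    """
    for name, table in (("reduced", reduced_events), ("oxidized", oxidized_events)):
        if len(table) < min_events:
            raise CalibrationError(
                f"{name} control has {len(table)} events; at least {min_events} required"
            )

    def _fit(table: pd.DataFrame) -> tuple[float, float, float]:
        x = table["i488"].to_numpy(dtype=float)
        y = table["i405"].to_numpy(dtype=float)
        if free_intercept:
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - (slope * x + intercept)
            sstot = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 - float(np.sum(resid**2)) / sstot if sstot > 0 else 1.0
            slope, r2 = float(slope), max(0.0, min(1.0, r2))
        else:
            slope, r2 = zero_intercept_slope(x, y)
        return slope, r2, float(x.mean())

    s_red, r2_red, mean488_red = _fit(reduced_events)
    s_ox, r2_ox, mean488_ox = _fit(oxidized_events)
    if s_ox <= s_red:
        raise CalibrationInversionError(
            f"oxidized slope ({s_ox:.4g}) <= reduced slope ({s_red:.4g}); "
            "control populations are likely swapped"
        )
    return CalibrationModel(
        i405_red_mean=s_red * mean488_red,
        i488_red_mean=mean488_red,
        i405_ox_mean=s_ox * mean488_ox,
        i488_ox_mean=mean488_ox,
        r_red=s_red,
        r_ox=s_ox,
        r2_red=r2_red,
        r2_ox=r2_ox,
        n_red=len(reduced_events),
        n_ox=len(oxidized_events),
        source_time=source_time,
    )
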