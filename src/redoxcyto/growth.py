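"""Recovery-growth statistics and division phenotypes of sorted subpopulations.

Sorted reduced/oxidized cells are regrown in fresh medium while OD600 is
logged; the module extracts the minimal doubling time (MDT) and lag duration
from each curve, and summarizes per-cell bud-scar counts and budding flags.

MDT follows the consecutive-point convention: within the logarithmic-growth
window, the slope of log10(OD) is computed between every pair of adjacent
samples and the steepest slope is converted to a doubling time.  A literal
mode that simply inverts the log10 slope (time per ten-fold increase) is
retained for compatibility with instrument software that reports it that way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import medfilt
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "GrowthCurve",
    "GrowthStats",
    "NoGrowthError",
    "detect_log_phase",
    "min_doubling_time",
    "lag_duration",
    "analyze_growth",
    "summarize_phenotypes",
]


class NoGrowthError(ValueError):
    """The curve never exhibits positive growth."""


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time series with sample metadata."""

    times_h: np.ndarray
    od600: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        od = np.asarray(self.od600, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "od600", od)
        if t.size < 4:
            raise ValueError("growth curve needs at least 4 points")
        if t.size != od.size:
            raise ValueError("times and OD series lengths differ")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(od > 0):
            raise ValueError("OD600 values must be positive")

    @classmethod
    def from_tsv(cls, path, **metadata) -> "GrowthCurve":
        df = pd.read_csv(path, sep="\t")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), metadata)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"time_h": self.times_h, "od600": self.od600}).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class GrowthStats:
    """Derived statistics of one recovery curve."""

    mdt_min: float
    lag_h: float
    log_window: tuple[int, int]
    slope_max: float  # log10(OD) per hour
    lag_censored: bool = False

    def __post_init__(self) -> None:
        if not self.mdt_min > 0:
            raise ValueError("mdt must be positive")
        if self.lag_h < 0:
            raise ValueError("lag must be nonnegative")


def _interval_slopes(times: np.ndarray, log_od: np.ndarray) -> np.ndarray:
    return np.diff(log_od) / np.diff(times)


def detect_log_phase(
    curve: GrowthCurve,
    *,
    slope_frac: float = 0.5,
    saturation_frac: float = 0.9,
    smooth: bool = True,
) -> tuple[int, int]:
    """Locate the logarithmic-growth window of a curve.

    Returns an inclusive point-index window ``(i0, i1)`` covering the maximal
    contiguous run of intervals whose smoothed log10(OD) slope is at least
    ``slope_frac`` of the global maximum and whose starting OD is below
    ``saturation_frac`` of the curve maximum (the plateau is excluded).  The
    run containing the steepest interval is chosen.

    Raises :class:`NoGrowthError` if the maximum slope is not positive.
    """
    od = curve.od600
    log_od = np.log10(medfilt(od, 3) if smooth and od.size >= 3 else od)
    slopes = _interval_slopes(curve.times_h, log_od)
    s_max = slopes.max()
    if s_max <= 0:
        raise NoGrowthError("curve shows no positive growth")
    eligible = (slopes >= slope_frac * s_max) & (od[:-1] <= saturation_frac * od.max())
    i_best = int(np.argmax(np.where(eligible, slopes, -np.inf)))
    if not eligible[i_best]:
        raise NoGrowthError("no eligible log-phase interval found")
    a = i_best
    while a > 0 and eligible[a - 1]:
        a -= 1
    b = i_best
    while b < eligible.size - 1 and eligible[b + 1]:
        b += 1
    return a, b + 1  # interval run [a, b] spans points a .. b+1


def min_doubling_time(
    curve: GrowthCurve,
    *,
    window: tuple[int, int] | None = None,
    literal_invert: bool = False,
    **phase_kwargs,
) -> GrowthStats:
    """Minimal doubling time from consecutive-point log10 slopes.

    Per-interval slopes of log10(OD) are computed between adjacent samples
    inside the log-phase window (detected automatically unless ``window`` is
    given); the steepest slope ``s`` yields ``MDT = log10(2) / s`` converted
    to minutes.  With ``literal_invert=True`` the slope is inverted directly
    (``1 / s``), i.e. the time for a ten-fold OD increase.
    """
    if window is None:
        window = detect_log_phase(curve, **phase_kwargs)
    i0, i1 = window
    if i1 - i0 < 1:
        raise ValueError("log-phase window must span at least 2 points")
    t = curve.times_h[i0 : i1 + 1]
    log_od = np.log10(curve.od600[i0 : i1 + 1])
    slopes = _interval_slopes(t, log_od)
    s_max = float(slopes.max())
    if s_max <= 0:
        raise NoGrowthError("no positive slope within the window")
    factor = 1.0 if literal_invert else np.log10(2.0)
    lag_h, censored = lag_duration(curve)
    return GrowthStats(
        mdt_min=60.0 * factor / s_max,
        lag_h=lag_h,
        log_window=(i0, i1),
        slope_max=s_max,
        lag_censored=censored,
    )


def lag_duration(curve: GrowthCurve, *, factor: float = 1.5) -> tuple[float, bool]:
    """Time until OD first exceeds ``factor`` times the initial OD.

    Linearly interpolated between samples.  Returns ``(lag_h, censored)``;
    a curve that never crosses the threshold is censored at its horizon.
    """
    target = factor * curve.od600[0]
    above = curve.od600 >= target
    if not above.any():
        return float(curve.times_h[-1]), True
    j = int(np.argmax(above))
    if j == 0:
        return 0.0, False
    t0, t1 = curve.times_h[j - 1], curve.times_h[j]
    y0, y1 = curve.od600[j - 1], curve.od600[j]
    lag = t0 + (target - y0) / (y1 - y0) * (t1 - t0)
    return float(lag), False


def analyze_growth(curve: GrowthCurve, **kwargs) -> GrowthStats:
    """Full per-curve statistics (MDT, lag, window)."""
    return min_doubling_time(curve, **kwargs)


def summarize_phenotypes(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-(age, subpopulation) scar and budding summary.

    Expects columns ``age_h``, ``subpopulation``, ``scar_count``,
    ``budding``.  Returns one row per group with the mean scar count, the
    oxidized/reduced scar-mean ratio at that age, and the budding fraction
    with its 95% Wilson confidence interval.  Empty groups are skipped with
    a warning.
    """
    rows = []
    for (age, subpop), grp in phenotypes.groupby(["age_h", "subpopulation"], sort=True):
        if len(grp) == 0:  # pragma: no cover - groupby drops empty groups
            warnings.warn(f"empty phenotype group ({age}, {subpop}); skipped")
            continue
        n = len(grp)
        n_bud = int(grp["budding"].sum())
        lo, hi = proportion_confint(n_bud, n, alpha=0.05, method="wilson")
        rows.append(
            {
                "age_h": age,
                "subpopulation": subpop,
                "n": n,
                "scar_mean": float(grp["scar_count"].mean()),
                "budding_fraction": n_bud / n,
                "budding_ci_low": float(lo),
                "budding_ci_high": float(hi),
            }
        )
    out = pd.DataFrame(rows)
    # oxidized / reduced scar-mean ratio per age
    ratios = {}
    for age, grp in out.groupby("age_h"):
        means = grp.set_index("subpopulation")["scar_mean"]
        if "oxidized" in means and "reduced" in means and means["reduced"] > 0:
            ratios[age] = means["oxidized"] / means["reduced"]
    out["scar_ratio_ox_over_red"] = out["age_h"].map(ratios)
    return out
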