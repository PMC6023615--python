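"""Single-cell OxD* time-series analysis.

Time-lapse imaging of Grx1-roGFP2 cells yields one OxD* series per tracked
cell.  The biology this module quantifies: below a commitment threshold,
cells transiently oxidize and then self-correct back toward a reduced
set-point; above the threshold oxidation is irreversible.  The threshold is
estimated by bracketing -- the highest OxD* a cell ever recovered from versus
the lowest OxD* from which a sustained, never-recovered rise began.  Budding
mothers hand their daughters an identical OxD* at separation, which the
concordance statistics test against a random re-pairing null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics.pairwise import nan_euclidean_distances

__all__ = [
    "CellTrajectory",
    "RecoveryEvent",
    "ThresholdEstimate",
    "UndefinedThresholdError",
    "detect_recovery_events",
    "estimate_threshold",
    "cluster_trajectories",
    "mother_daughter_concordance",
    "trajectories_to_long",
    "trajectories_from_long",
]


class UndefinedThresholdError(ValueError):
    """No recovery events and no commitments: the threshold is undefined."""


@dataclass(frozen=True)
class CellTrajectory:
    """One cell's OxD* series with optional lineage links.

    ``oxd_star`` may exceed [0, 1]; per-cell normalization against
    population-average endpoints inflates the scale for outlier cells.
    """

    cell_id: str
    times_min: np.ndarray
    oxd_star: np.ndarray
    area: np.ndarray | None = None
    mother_id: str | None = None
    birth_time_min: float | None = None
    fate: str = "alive"  # alive | oxidized-death | signal-lost

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        x = np.asarray(self.oxd_star, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "oxd_star", x)
        if t.size != x.size:
            raise ValueError(f"{self.cell_id}: times and series lengths differ")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError(f"{self.cell_id}: times must be strictly increasing")
        if self.area is not None and np.asarray(self.area).size != t.size:
            raise ValueError(f"{self.cell_id}: area series length differs")

    def value_at(self, time_min: float) -> float:
        """Linearly interpolated OxD* at a time inside the tracked span."""
        if time_min < self.times_min[0] or time_min > self.times_min[-1]:
            return float("nan")
        return float(np.interp(time_min, self.times_min, self.oxd_star))


@dataclass(frozen=True)
class RecoveryEvent:
    peak_time_min: float
    peak_value: float
    trough_value: float


@dataclass(frozen=True)
class ThresholdEstimate:
    """Bracketed estimate of the oxidation-commitment threshold."""

    theta_hat: float
    max_recovered_from: float | None
    min_committed_from: float | None
    n_recovery_events: int
    n_commitments: int
    bootstrap_ci: tuple[float, float] | None = None
    one_sided: str | None = None  # None | "recovery-only" | "commitment-only"

    def __post_init__(self) -> None:
        if (
            self.max_recovered_from is not None
            and self.min_committed_from is not None
            and not (
                min(self.max_recovered_from, self.min_committed_from)
                <= self.theta_hat
                <= max(self.max_recovered_from, self.min_committed_from)
            )
        ):
            raise ValueError("theta_hat must lie between the two brackets")


def detect_recovery_events(
    traj: CellTrajectory, delta: float = 0.1, window: int | None = None
) -> list[RecoveryEvent]:
    """Self-correction events: a local peak followed by a drop of >= delta.

    A recovery event is a local maximum of the series followed, within
    ``window`` frames (unlimited by default), by a value at least ``delta``
    lower.  Scanning resumes after each event's trough, so overlapping dips
    are not double-counted.  Returns an empty list when nothing qualifies.
    """
    x = traj.oxd_star
    if x.size < 3:
        raise ValueError("need at least 3 frames to detect recovery events")
    events: list[RecoveryEvent] = []
    i = 0
    n = x.size
    while i < n - 1:
        # local maximum (plateaus count via >=)
        if (i == 0 or x[i] >= x[i - 1]) and x[i] >= x[i + 1]:
            stop = n if window is None else min(n, i + 1 + window)
            # the dip belonging to this peak ends where the series first
            # exceeds the peak again (a new rise starts a new excursion)
            j = i + 1
            while j < stop and x[j] <= x[i]:
                j += 1
            seg = x[i + 1 : j]
            if seg.size:
                j_rel = int(np.argmin(seg))
                trough = float(seg[j_rel])
                if x[i] - trough >= delta:
                    events.append(
                        RecoveryEvent(
                            peak_time_min=float(traj.times_min[i]),
                            peak_value=float(x[i]),
                            trough_value=trough,
                        )
                    )
                    i = i + 1 + j_rel  # resume at the trough
                    continue
        i += 1
    return events


def _commitment_candidates(x: np.ndarray, delta: float) -> np.ndarray:
    """Visited values that were never escaped and sit on a sustained rise.

    A frame i is a candidate when the series later rises by at least
    ``delta`` above x[i] (it is part of a genuine rise, not flat noise) and
    never afterwards falls ``delta`` or more below x[i] (the cell never
    recovered from that level).  Returns the sorted candidate values; which
    of them count as commitments is decided at the ensemble level, where
    candidates at levels other cells demonstrably escaped from are
    discarded.
    """
    n = x.size
    if n < 2:
        return np.empty(0)
    suffix_min = np.minimum.accumulate(x[::-1])[::-1]
    suffix_max = np.maximum.accumulate(x[::-1])[::-1]
    future_min = suffix_min[1:]
    future_max = suffix_max[1:]
    xi = x[:-1]
    ok = (future_max >= xi + delta) & (future_min > xi - delta)
    return np.sort(xi[ok])


def estimate_threshold(
    trajs: list[CellTrajectory],
    delta: float = 0.1,
    *,
    n_boot: int = 1000,
    seed: int = 0,
) -> ThresholdEstimate:
    """Bracket the commitment threshold from an ensemble of trajectories.

    ``max_recovered_from`` is the highest peak any cell recovered from (a
    later drop of >= ``delta``); ``min_committed_from`` is the lowest OxD*
    level that some cell visited on a sustained rise and never recovered
    from, *above* the recovered bracket -- levels at or below the highest
    recovered peak are demonstrably escapable, so a never-recovered visit
    there (e.g. the foot of a final ascent, or a transient low dip that was
    simply never revisited) is not evidence of commitment.  The point
    estimate is the midpoint of the two brackets; a bootstrap over cells
    gives the confidence interval.  Cells with ``fate == "signal-lost"``
    are excluded (their truncated series say nothing about commitment).

    With only one side observed the estimate is that bound, flagged
    ``one_sided``; with neither, :class:`UndefinedThresholdError` is raised.
    """
    usable = sorted(
        (t for t in trajs if t.fate != "signal-lost"), key=lambda t: t.cell_id
    )
    peaks_per_cell: list[list[float]] = []
    candidates_per_cell: list[np.ndarray] = []
    for t in usable:
        events = detect_recovery_events(t, delta) if t.oxd_star.size >= 3 else []
        peaks_per_cell.append([e.peak_value for e in events])
        candidates_per_cell.append(_commitment_candidates(t.oxd_star, delta))

    def _estimate(idx: np.ndarray) -> tuple[float | None, float | None]:
        peaks = [p for i in idx for p in peaks_per_cell[i]]
        max_rec = max(peaks) if peaks else None
        floor = -np.inf if max_rec is None else max_rec
        best = None
        for i in idx:
            cand = candidates_per_cell[i]
            pos = np.searchsorted(cand, floor, side="right")
            if pos < cand.size and (best is None or cand[pos] < best):
                best = float(cand[pos])
        return max_rec, best

    all_idx = np.arange(len(usable))
    max_rec, min_com = _estimate(all_idx)
    n_rec = sum(len(p) for p in peaks_per_cell)
    floor = -np.inf if max_rec is None else max_rec
    n_com = sum(
        int(np.searchsorted(c, floor, side="right") < c.size) for c in candidates_per_cell
    )
    if max_rec is None and min_com is None:
        raise UndefinedThresholdError(
            "no recovery events and no commitments in the ensemble"
        )
    if max_rec is None:
        theta, one_sided = float(min_com), "commitment-only"
    elif min_com is None:
        theta, one_sided = float(max_rec), "recovery-only"
    else:
        theta, one_sided = (max_rec + min_com) / 2.0, None

    ci = None
    if n_boot > 0 and len(usable) > 1:
        rng = np.random.default_rng(seed)
        boot = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(usable), size=len(usable))
            mr, mc = _estimate(idx)
            if mr is not None and mc is not None:
                boot.append((mr + mc) / 2.0)
            elif mr is not None or mc is not None:
                boot.append(mr if mr is not None else mc)
        if boot:
            ci = tuple(np.percentile(boot, [2.5, 97.5]))

    return ThresholdEstimate(
        theta_hat=theta,
        max_recovered_from=max_rec,
        min_committed_from=min_com,
        n_recovery_events=n_rec,
        n_commitments=n_com,
        bootstrap_ci=ci,
        one_sided=one_sided,
    )


def cluster_trajectories(
    trajs: list[CellTrajectory], k: int, *, grid: np.ndarray | None = None
) -> np.ndarray:
    """Agglomerative average-linkage clustering of resampled trajectories.

    Each trajectory is linearly interpolated onto a common time grid (by
    default spanning the ensemble at the median frame interval); frames
    outside a cell's tracked span are missing and ignored pairwise in the
    Euclidean distances.  Ties are broken deterministically by sorting cells
    lexicographically by id before linkage.  Returns integer labels
    (1..k) aligned with the input order.
    """
    if k > len(trajs):
        raise ValueError(f"k={k} exceeds the number of trajectories ({len(trajs)})")
    if k < 1:
        raise ValueError("k must be >= 1")
    order = np.argsort([t.cell_id for t in trajs], kind="stable")
    ordered = [trajs[i] for i in order]
    if grid is None:
        t0 = min(t.times_min[0] for t in ordered)
        t1 = max(t.times_min[-1] for t in ordered)
        dts = np.concatenate([np.diff(t.times_min) for t in ordered if t.times_min.size > 1])
        dt = float(np.median(dts)) if dts.size else max(t1 - t0, 1.0)
        grid = np.arange(t0, t1 + dt / 2, dt)
    mat = np.full((len(ordered), grid.size), np.nan)
    for i, t in enumerate(ordered):
        inside = (grid >= t.times_min[0]) & (grid <= t.times_min[-1])
        mat[i, inside] = np.interp(grid[inside], t.times_min, t.oxd_star)
    if len(ordered) == 1:
        labels_ordered = np.array([1])
    else:
        dist = nan_euclidean_distances(mat)
        np.fill_diagonal(dist, 0.0)
        # tracks with no overlapping frames are maximally dissimilar
        bad = ~np.isfinite(dist)
        if bad.any():
            finite_max = float(np.nanmax(np.where(bad, np.nan, dist)))
            dist[bad] = 2.0 * finite_max if np.isfinite(finite_max) and finite_max > 0 else 1.0
        dist = (dist + dist.T) / 2.0  # exact symmetry for squareform
        Z = linkage(squareform(dist, checks=False), method="average")
        labels_ordered = fcluster(Z, t=k, criterion="maxclust")
    labels = np.empty(len(trajs), dtype=int)
    labels[order] = labels_ordered
    return labels


def mother_daughter_concordance(
    trajs: list[CellTrajectory], delta: float = 0.1, offset_min: float = 60.0
) -> pd.DataFrame:
    """Per-pair inheritance statistics at and after mother-daughter separation.

    For every linked pair with overlapping frames: the absolute OxD*
    difference at the daughter's first (separation) frame, the difference
    ``offset_min`` minutes later (NaN if either track has ended), and a flag
    for daughters that self-corrected their inherited OxD* by at least
    ``delta`` after separation.

    Raises ``ValueError`` when no lineage links are present.
    """
    by_id = {t.cell_id: t for t in trajs}
    rows = []
    for d in trajs:
        if d.mother_id is None or d.mother_id not in by_id:
            continue
        m = by_id[d.mother_id]
        t_sep = float(d.times_min[0])
        m_at_sep = m.value_at(t_sep)
        if np.isnan(m_at_sep):
            continue
        d0 = float(d.oxd_star[0])
        later = t_sep + offset_min
        rows.append(
            {
                "daughter_id": d.cell_id,
                "mother_id": m.cell_id,
                "separation_min": t_sep,
                "abs_delta_at_separation": abs(d0 - m_at_sep),
                "abs_delta_at_offset": abs(d.value_at(later) - m.value_at(later)),
                "daughter_recovered": bool((d0 - d.oxd_star.min()) >= delta),
                "mother_fate": m.fate,
                "daughter_fate": d.fate,
            }
        )
    if not rows:
        raise ValueError("no mother-daughter pairs with overlapping frames")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# long-format IO
# ---------------------------------------------------------------------------


def trajectories_to_long(trajs: list[CellTrajectory]) -> pd.DataFrame:
    """Long-format table (cell_id, time_min, oxd_star, lineage, fate)."""
    frames = []
    for t in trajs:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": t.cell_id,
                    "time_min": t.times_min,
                    "oxd_star": t.oxd_star,
                    "area": t.area if t.area is not None else np.nan,
                    "mother_id": t.mother_id or "",
                    "birth_time_min": t.birth_time_min
                    if t.birth_time_min is not None
                    else np.nan,
                    "fate": t.fate,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def trajectories_from_long(df: pd.DataFrame) -> list[CellTrajectory]:
    """Rebuild trajectories from a long-format table.

    Accepts either a precomputed ``oxd_star`` column or per-frame
    ``i405_mean`` / ``i488_mean`` columns plus an imaging calibration applied
    upstream.
    """
    out = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("time_min")
        mother = grp["mother_id"].iloc[0] if "mother_id" in grp else ""
        birth = grp["birth_time_min"].iloc[0] if "birth_time_min" in grp else np.nan
        area = grp["area"].to_numpy() if "area" in grp and grp["area"].notna().all() else None
        out.append(
            CellTrajectory(
                cell_id=str(cell_id),
                times_min=grp["time_min"].to_numpy(),
                oxd_star=grp["oxd_star"].to_numpy(),
                area=area,
                mother_id=str(mother) if isinstance(mother, str) and mother else None,
                birth_time_min=None if pd.isna(birth) else float(birth),
                fate=str(grp["fate"].iloc[0]) if "fate" in grp else "alive",
            )
        )
    return out
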