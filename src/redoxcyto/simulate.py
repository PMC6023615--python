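"""Seeded generators emulating the study's measurement types.

Every downstream stage of the pipeline can be exercised on data from this
module: two-channel cytometry events (calibration controls, aging cultures
with dead and probe-negative cells), OD600 recovery-growth curves, per-cell
OxD* time-lapse trajectories with division inheritance, phenotype tables
(bud-scar counts, budding flags), and paired protein/RNA abundance matrices
with planted redox-dependent and uncoupled features.

All generators are deterministic given (config, seed); each carries hidden
ground-truth columns so parameter-recovery tests can compare pipeline output
against the generating truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import GrowthCurve
from .trajectories import CellTrajectory

__all__ = [
    "AgingSimConfig",
    "TrajSimConfig",
    "OmicsSimConfig",
    "gen_calibration_controls",
    "gen_aging_culture",
    "gen_growth_curve",
    "gen_trajectories",
    "gen_omics",
    "gen_phenotypes",
    "GROWTH_PARAMS",
    "BUDDING_FRACTIONS",
]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgingSimConfig:
    """Parameters of the synthetic cytometry event stream.

    Control populations are linear in the 405-vs-488 plane with slopes
    ``slope_red`` / ``slope_ox`` (the chemically clamped endpoints).  Aging
    cultures are mixtures of reduced, oxidized, intermediate, dead, and
    probe-negative events; the oxidized fraction among live probe-positive
    cells follows a logistic curve of culture age whose steepest rise falls
    in the 48-72 hr interval.  In-culture oxidized cells are drawn around
    their own ratio mode (``ratio_ox_culture``, default 7) rather than the
    diamide-control slope: untreated oxidized cells sit at noticeably higher
    405/488 ratios than the clamped control.
    """

    slope_red: float = 0.6
    slope_ox: float = 3.57
    cv_noise: float = 0.05
    expr_meanlog: float = math.log(100.0)
    expr_sdlog: float = 0.4
    # in-culture oxidized ratio mode (distinct from the diamide control slope)
    ratio_ox_culture: float = 7.0
    ratio_ox_sdlog: float = 0.25
    # intermediate (between-gates) events
    frac_intermediate: float = 0.02
    int_ratio_center: float = 1.8
    int_ratio_sdlog: float = 0.15
    # oxidized fraction among live probe-positive cells: logistic in age
    ox_frac_max: float = 0.45
    ox_midpoint_h: float = 60.0
    ox_steepness_h: float = 10.0
    # dead / probe-negative fractions (nondecreasing in age)
    dead_base: float = 0.04
    dead_rate_per_h: float = 0.0015
    probe_neg_base: float = 0.05
    probe_neg_rate_per_h: float = 0.0005
    # viability-dye channel
    pi_live_mean: float = 100.0
    pi_dead_mean: float = 5000.0
    pi_sdlog: float = 0.3
    # probe-negative autofluorescence floor
    probe_neg_meanlog: float = math.log(8.0)
    probe_neg_sdlog: float = 0.5
    # bud-scar marker channel levels (high for multiply divided cells)
    marker_high_mean: float = 2000.0
    marker_low_mean: float = 200.0
    marker_sdlog: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.slope_ox > self.slope_red > 0:
            raise ValueError("require slope_ox > slope_red > 0")
        for t in (0.0, 24.0, 48.0, 72.0, 96.0):
            fd, fp = self.frac_dead(t), self.frac_probe_neg(t)
            if not (0 <= fd <= 1 and 0 <= fp <= 1 and fd + fp <= 1):
                raise ValueError(f"dead/probe-negative fractions invalid at t={t}")
            if not 0 <= self.frac_oxidized(t) <= 1:
                raise ValueError(f"oxidized fraction outside [0,1] at t={t}")
        if not 0 <= self.frac_intermediate <= 1:
            raise ValueError("frac_intermediate must lie in [0,1]")

    def frac_oxidized(self, t: float) -> float:
        """Oxidized fraction among live probe-positive cells at age t (hours)."""
        return self.ox_frac_max / (1.0 + math.exp(-(t - self.ox_midpoint_h) / self.ox_steepness_h))

    def frac_dead(self, t: float) -> float:
        return min(0.9, self.dead_base + self.dead_rate_per_h * t)

    def frac_probe_neg(self, t: float) -> float:
        return min(0.9, self.probe_neg_base + self.probe_neg_rate_per_h * t)


@dataclass(frozen=True)
class TrajSimConfig:
    """Parameters of the single-cell OxD* trajectory simulator.

    Below the commitment threshold ``theta`` a cell's OxD* is mean-reverting
    around ``baseline`` (excursions up to just under theta can self-correct);
    at or above theta oxidation is absorbing and strictly increasing
    (``drift_up`` per frame).  Budding copies the mother's current OxD* to
    the daughter exactly at separation; the budding rate decreases with
    oxidation and is zero at/above theta.
    """

    theta: float = 0.7
    baseline: float = 0.4
    reversion_rate: float = 0.15
    step_sd: float = 0.05
    drift_up: float = 0.03
    dt_min: float = 10.0
    horizon_h: float = 12.0
    division_rate_per_h: float = 0.25  # at OxD* = 0, falling linearly to 0 at theta
    frac_born_oxidized: float = 0.10
    born_ox_low: float = 0.72
    born_ox_high: float = 0.95
    frac_signal_lost: float = 0.05
    death_level: float = 1.2
    max_cells: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.baseline < self.theta < 1.0):
            raise ValueError("require 0 < baseline < theta < 1")
        if not self.drift_up > 0:
            raise ValueError("drift_up must be > 0")

    def division_rate(self, oxd: float) -> float:
        """Per-hour budding rate at a given OxD*."""
        return self.division_rate_per_h * max(0.0, 1.0 - oxd / self.theta)


@dataclass(frozen=True)
class OmicsSimConfig:
    """Parameters of the paired protein/RNA abundance simulator.

    The design mirrors the sorting experiment: two redox states (reduced,
    oxidized) at two culture ages (48, 72 hr) with three biological
    replicates each.  ``n_planted_de`` features carry a redox effect that is
    consistent across age (so samples cluster by redox status before age);
    features named in ``planted_uncoupled`` have protein and transcript
    effects of opposite sign -- by default an Hsp30-like and a Yro2-like
    feature whose protein is up in the reduced cells while the transcript is
    up in the oxidized cells.
    """

    n_features: int = 1500
    n_planted_de: int = 150
    lfc_mean: float = 2.0
    lfc_sd: float = 0.5
    replicates: int = 3
    ages: tuple[int, ...] = (48, 72)
    noise_sd: float = 0.25
    age_effect_sd: float = 0.05
    planted_uncoupled: tuple[str, ...] = ("HSP30like", "YRO2like")
    uncoupled_protein_lfc: float = -2.5  # protein up in reduced cells
    nb_dispersion: float = 0.1
    rna_base_meanlog2: float = 7.0
    rna_base_sdlog2: float = 1.5
    protein_base_mean: float = 24.0
    protein_base_sd: float = 2.0
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_de > self.n_features:
            raise ValueError("n_planted_de cannot exceed n_features")
        if self.replicates < 2:
            raise ValueError("at least 2 replicates per group are required")


# ---------------------------------------------------------------------------
# cytometry generators
# ---------------------------------------------------------------------------


def _expr_488(rng: np.random.Generator, cfg: AgingSimConfig, n: int) -> np.ndarray:
    return rng.lognormal(cfg.expr_meanlog, cfg.expr_sdlog, size=n)


def _pi(rng: np.random.Generator, cfg: AgingSimConfig, n: int, mean: float) -> np.ndarray:
    # lognormal with the requested arithmetic mean
    meanlog = math.log(mean) - cfg.pi_sdlog**2 / 2.0
    return rng.lognormal(meanlog, cfg.pi_sdlog, size=n)


def gen_calibration_controls(
    cfg: AgingSimConfig, n_events: int = 10_000, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fully reduced (DTT-like) and fully oxidized (diamide-like) controls.

    Each event's 488 intensity is a log-normal probe-expression draw; the 405
    intensity sits on the control slope with multiplicative Gaussian noise
    of coefficient of variation ``cv_noise``.  Returns ``(reduced,
    oxidized)`` event tables with ``i405``, ``i488``, ``pi`` and ``marker``
    columns.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    def _control(slope: float) -> pd.DataFrame:
        i488 = _expr_488(rng, cfg, n_events)
        i405 = slope * i488 * (1.0 + rng.normal(0.0, cfg.cv_noise, size=n_events))
        df = pd.DataFrame(
            {
                "i405": np.maximum(i405, 1e-9),
                "i488": i488,
                "pi": _pi(rng, cfg, n_events, cfg.pi_live_mean),
                "marker": np.zeros(n_events),
            }
        )
        return df

    reduced = _control(cfg.slope_red)
    oxidized = _control(cfg.slope_ox)
    reduced.attrs.update({"control": "reduced", "n_events": n_events})
    oxidized.attrs.update({"control": "oxidized", "n_events": n_events})
    return reduced, oxidized


_STATES = ("dead", "probe_negative", "reduced", "oxidized", "intermediate")


def gen_aging_culture(
    cfg: AgingSimConfig,
    t: float,
    n_events: int = 10_000,
    seed: int | None = None,
    include_marker: bool = True,
) -> pd.DataFrame:
    """One cytometry sample of a chronologically aging culture at age ``t``.

    Events are drawn as dead / probe-negative / reduced / oxidized /
    intermediate with probabilities from the config at ``t``.  Dead events
    carry a high viability-dye signal; probe-negative events sit at the
    autofluorescence floor on both excitation channels; a small intermediate
    fraction falls between the ratio gates.  The hidden ``truth_state``
    column records the generating state of every event.
    """
    if t < 0:
        raise ValueError("culture age must be nonnegative")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    p_dead = cfg.frac_dead(t)
    p_pneg = cfg.frac_probe_neg(t)
    p_live = 1.0 - p_dead - p_pneg
    if p_live < 0:
        raise ValueError("dead + probe-negative fractions exceed 1")
    f_ox = cfg.frac_oxidized(t)
    p_int = p_live * cfg.frac_intermediate
    p_ox = p_live * (1.0 - cfg.frac_intermediate) * f_ox
    p_red = p_live * (1.0 - cfg.frac_intermediate) * (1.0 - f_ox)

    probs = np.array([p_dead, p_pneg, p_red, p_ox, p_int])
    state_idx = rng.choice(len(_STATES), size=n_events, p=probs / probs.sum())
    state = np.array(_STATES)[state_idx]

    i405 = np.empty(n_events)
    i488 = np.empty(n_events)
    pi = np.empty(n_events)
    marker = np.empty(n_events)

    for s in _STATES:
        mask = state == s
        n = int(mask.sum())
        if n == 0:
            continue
        if s == "probe_negative":
            i405[mask] = rng.lognormal(cfg.probe_neg_meanlog, cfg.probe_neg_sdlog, n)
            i488[mask] = rng.lognormal(cfg.probe_neg_meanlog, cfg.probe_neg_sdlog, n)
        else:
            expr = _expr_488(rng, cfg, n)
            if s == "reduced":
                ratio = cfg.slope_red * (1.0 + rng.normal(0.0, cfg.cv_noise, n))
            elif s == "oxidized":
                ratio = rng.lognormal(math.log(cfg.ratio_ox_culture), cfg.ratio_ox_sdlog, n)
            elif s == "intermediate":
                ratio = rng.lognormal(math.log(cfg.int_ratio_center), cfg.int_ratio_sdlog, n)
            else:  # dead: broad, oxidation-shifted ratios; gated out by the dye anyway
                ratio = rng.lognormal(math.log(4.0), 0.6, n)
            i488[mask] = expr
            i405[mask] = np.maximum(ratio, 1e-9) * expr
        pi[mask] = _pi(rng, cfg, n, cfg.pi_dead_mean if s == "dead" else cfg.pi_live_mean)
        mean = cfg.marker_high_mean if s == "oxidized" else cfg.marker_low_mean
        marker[mask] = rng.lognormal(math.log(mean), cfg.marker_sdlog, n)

    df = pd.DataFrame(
        {"i405": i405, "i488": i488, "pi": pi, "truth_state": state}
    )
    if include_marker:
        df["marker"] = marker
    df.attrs.update({"age_h": float(t), "n_events": n_events, "strain": "synthetic-WT"})
    return df


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

#: per (subpopulation, age): minimal doubling time (min), lag (h)
GROWTH_PARAMS: dict[tuple[str, int], tuple[float, float]] = {
    ("reduced", 48): (90.0, 2.0),
    ("oxidized", 48): (125.0, 2.2),
    ("reduced", 72): (95.0, 2.5),
    ("oxidized", 72): (135.0, 2.7),
    ("reduced", 96): (150.0, 5.5),
    ("oxidized", 96): (155.0, 6.0),
}


def gen_growth_curve(
    kind: str,
    age: int,
    seed: int = 0,
    *,
    od0: float = 0.1,
    carrying_od: float = 1.5,
    duration_h: float = 24.0,
    dt_min: float = 15.0,
    noise_sdlog: float = 0.01,
) -> GrowthCurve:
    """Lag-logistic OD600 recovery curve of a sorted subpopulation.

    ``kind`` is ``"reduced_sorted"`` or ``"oxidized_sorted"``; ``age`` is the
    culture age at sorting (48, 72 or 96 hr).  Defaults encode the sorted
    subpopulations' qualitative pattern: reduced cells double faster than
    oxidized at 48 and 72 hr with comparable lags, while at 96 hr both
    groups share similar doubling times after longer lags.
    """
    subpop = kind.replace("_sorted", "")
    key = (subpop, int(age))
    if key not in GROWTH_PARAMS:
        raise ValueError(f"unsupported (kind, age): {kind!r}, {age!r}")
    mdt_min, lag_h = GROWTH_PARAMS[key]
    mu = math.log(2.0) / (mdt_min / 60.0)  # per hour
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_h + 1e-9, dt_min / 60.0)
    grown = np.clip(times - lag_h, 0.0, None)
    # logistic growth from od0 toward carrying_od after the lag
    od = carrying_od * od0 * np.exp(mu * grown) / (
        carrying_od + od0 * (np.exp(mu * grown) - 1.0)
    )
    od = od * rng.lognormal(0.0, noise_sdlog, size=od.size)
    return GrowthCurve(
        times_h=times,
        od600=od,
        metadata={"subpopulation": subpop, "age_h": float(age), "seed": seed},
    )


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def gen_trajectories(
    cfg: TrajSimConfig, n_cells: int, seed: int | None = None
) -> list[CellTrajectory]:
    """Simulate threshold-governed OxD* trajectories with division inheritance.

    ``n_cells`` founder cells are started at frame 0 (a configurable fraction
    born already above the threshold); daughters produced by budding are
    appended to the returned list with lineage links, their first frame
    copying the mother's OxD* at separation exactly.  Below ``theta``
    dynamics are mean-reverting with Gaussian steps; at/above ``theta``
    oxidation is absorbing and strictly increasing until the death level.
    Cells may instead lose probe signal (``fate == "signal-lost"``), which
    truncates the series without an oxidation rise.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_frames = int(round(cfg.horizon_h * 60.0 / cfg.dt_min)) + 1
    times = np.arange(n_frames) * cfg.dt_min
    p_div_frame_base = cfg.division_rate_per_h * cfg.dt_min / 60.0

    # (cell_id, start_frame, start_value, mother_id)
    queue: list[tuple[str, int, float, str | None]] = []
    for i in range(n_cells):
        if rng.random() < cfg.frac_born_oxidized:
            start = rng.uniform(cfg.born_ox_low, cfg.born_ox_high)
        else:
            start = cfg.baseline
        queue.append((f"cell{i:04d}", 0, start, None))

    out: list[CellTrajectory] = []
    next_daughter = 0
    while queue:
        cell_id, start_frame, start_value, mother_id = queue.pop(0)
        lost_at = None
        if rng.random() < cfg.frac_signal_lost:
            # probe loss strikes at a uniform later frame
            remaining = n_frames - start_frame
            if remaining > 3:
                lost_at = start_frame + int(rng.integers(2, remaining))
        x = start_value
        values = [x]
        fate = "alive"
        end_frame = n_frames - 1
        for k in range(start_frame + 1, n_frames):
            if lost_at is not None and k >= lost_at and x < cfg.theta:
                fate = "signal-lost"
                end_frame = k - 1
                break
            if x >= cfg.theta:
                x = x + cfg.drift_up * rng.uniform(0.5, 1.5)
            else:
                x = x + cfg.reversion_rate * (cfg.baseline - x) + rng.normal(0.0, cfg.step_sd)
                x = max(x, 0.0)
            values.append(x)
            if x >= cfg.death_level:
                fate = "oxidized-death"
                end_frame = k
                break
            # budding: rate decreases with oxidation, zero at/above theta
            if x < cfg.theta and len(out) + len(queue) < cfg.max_cells:
                p_div = p_div_frame_base * max(0.0, 1.0 - x / cfg.theta)
                if rng.random() < p_div and k < n_frames - 1:
                    did = f"daughter{next_daughter:04d}"
                    next_daughter += 1
                    # daughter's first frame copies the mother's OxD* exactly
                    queue.append((did, k, x, cell_id))
        else:
            end_frame = n_frames - 1
        values_arr = np.array(values[: end_frame - start_frame + 1])
        out.append(
            CellTrajectory(
                cell_id=cell_id,
                times_min=times[start_frame : start_frame + values_arr.size].copy(),
                oxd_star=values_arr,
                mother_id=mother_id,
                birth_time_min=float(times[start_frame]) if mother_id is not None else None,
                fate=fate,
            )
        )
    return out


# ---------------------------------------------------------------------------
# omics
# ---------------------------------------------------------------------------


def _sample_sheet(cfg: OmicsSimConfig) -> pd.DataFrame:
    rows = []
    for redox in ("reduced", "oxidized"):
        for age in cfg.ages:
            for rep in range(1, cfg.replicates + 1):
                rows.append(
                    {
                        "sample": f"{redox}_{age}h_r{rep}",
                        "redox": redox,
                        "age": age,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample")


def gen_omics(cfg: OmicsSimConfig, seed: int | None = None):
    """Paired protein-intensity and transcript-count matrices.

    Returns ``(protein, rna, truth)`` where ``protein`` and ``rna`` are
    :class:`~redoxcyto.omics.AbundanceMatrix` objects over the same feature
    set and sample design, and ``truth`` is a per-feature table of planted
    log2 effects (positive = up in the oxidized cells).  Transcript effects
    equal protein effects except for the configured uncoupled features,
    whose transcript moves opposite to the protein.
    """
    from .omics import AbundanceMatrix

    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    samples = _sample_sheet(cfg)
    n_bg = cfg.n_features - cfg.n_planted_de - len(cfg.planted_uncoupled)
    if n_bg < 0:
        raise ValueError("n_features too small for planted features")

    names = (
        [f"DE{i:04d}" for i in range(cfg.n_planted_de)]
        + list(cfg.planted_uncoupled)
        + [f"BG{i:04d}" for i in range(n_bg)]
    )
    lfc_prot = np.zeros(len(names))
    signs = rng.choice([-1.0, 1.0], size=cfg.n_planted_de)
    lfc_prot[: cfg.n_planted_de] = signs * rng.normal(cfg.lfc_mean, cfg.lfc_sd, cfg.n_planted_de)
    k0 = cfg.n_planted_de
    lfc_prot[k0 : k0 + len(cfg.planted_uncoupled)] = cfg.uncoupled_protein_lfc
    lfc_rna = lfc_prot.copy()
    lfc_rna[k0 : k0 + len(cfg.planted_uncoupled)] = -cfg.uncoupled_protein_lfc

    sign_col = np.where(samples["redox"].to_numpy() == "oxidized", 0.5, -0.5)
    age_shift = rng.normal(0.0, cfg.age_effect_sd, size=len(names))
    age_col = np.where(samples["age"].to_numpy() == samples["age"].to_numpy().max(), 0.5, -0.5)

    # protein: log2 LFQ-like intensities
    base_p = rng.normal(cfg.protein_base_mean, cfg.protein_base_sd, size=len(names))
    prot = (
        base_p[:, None]
        + lfc_prot[:, None] * sign_col[None, :]
        + age_shift[:, None] * age_col[None, :]
        + rng.normal(0.0, cfg.noise_sd, size=(len(names), len(samples)))
    )
    if cfg.dropout_rate > 0:
        drop = rng.random(prot.shape) < cfg.dropout_rate
        prot = np.where(drop, np.nan, prot)
    protein_df = pd.DataFrame(prot, index=names, columns=samples.index)

    # rna: negative-binomial counts around planted log2 means
    base_r = rng.normal(cfg.rna_base_meanlog2, cfg.rna_base_sdlog2, size=len(names))
    mu = 2.0 ** (
        base_r[:, None]
        + lfc_rna[:, None] * sign_col[None, :]
        + age_shift[:, None] * age_col[None, :]
    )
    n_param = 1.0 / cfg.nb_dispersion
    p_param = n_param / (n_param + mu)
    counts = rng.negative_binomial(n_param, p_param)
    rna_df = pd.DataFrame(counts.astype(np.int64), index=names, columns=samples.index)

    truth = pd.DataFrame(
        {
            "feature": names,
            "planted": [i < k0 + len(cfg.planted_uncoupled) for i in range(len(names))],
            "uncoupled": [k0 <= i < k0 + len(cfg.planted_uncoupled) for i in range(len(names))],
            "true_lfc_protein": lfc_prot,
            "true_lfc_rna": lfc_rna,
        }
    ).set_index("feature")

    protein = AbundanceMatrix(values=protein_df, samples=samples.copy(), modality="protein")
    rna = AbundanceMatrix(values=rna_df, samples=samples.copy(), modality="rna")
    return protein, rna, truth


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

#: budding fraction per (age, subpopulation)
BUDDING_FRACTIONS: dict[tuple[int, str], float] = {
    (48, "oxidized"): 0.10,
    (48, "reduced"): 0.30,
    (72, "oxidized"): 0.09,
    (72, "reduced"): 0.21,
    (96, "oxidized"): 0.06,
    (96, "reduced"): 0.15,
}


def gen_phenotypes(
    n_per_group: int,
    seed: int = 0,
    *,
    ages: tuple[int, ...] = (48, 72, 96),
    scar_mean_reduced: float = 0.7,
    scar_ratio: float = 3.75,
    budding_fractions: dict[tuple[int, str], float] | None = None,
) -> pd.DataFrame:
    """Per-cell bud-scar counts and budding flags for sorted subpopulations.

    Scar counts are Poisson; the oxidized group's mean is ``scar_ratio``
    times the reduced mean (oxidized cells have divided several-fold more
    often).  Budding flags are Bernoulli with per-(age, subpopulation)
    fractions defaulting to the sorted-culture budding rates.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    fractions = BUDDING_FRACTIONS if budding_fractions is None else budding_fractions
    rng = np.random.default_rng(seed)
    rows = []
    for age in ages:
        for subpop in ("reduced", "oxidized"):
            mean = scar_mean_reduced * (scar_ratio if subpop == "oxidized" else 1.0)
            scars = rng.poisson(mean, size=n_per_group)
            budding = rng.random(n_per_group) < fractions[(age, subpop)]
            rows.append(
                pd.DataFrame(
                    {
                        "age_h": age,
                        "subpopulation": subpop,
                        "scar_count": scars,
                        "budding": budding,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
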