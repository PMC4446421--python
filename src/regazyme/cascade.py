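"""Deterministic ODE model of the regazyme signaling pathway.

Signal s(t) → ligand-induced self-cleavage → released riboregulator →
translation activation → reporter protein.  The minimal three-state model
uses first-order kinetics with a quasi-steady-state treatment of
translation initiation:

    dRu/dt = beta_R - (k(s) + delta_R) * Ru        (uncleaved regazyme)
    dRa/dt = k(s) * Ru - delta_R * Ra              (released riboregulator)
    dG/dt  = alpha_G * Ra / (K_RU + Ra) - delta_G * G   (reporter)

with the signal-dependent cleavage rate k(s) = k_leak + k_cat * s/(K_s + s)
(single-site saturation).  The defaults encode the measured time scales of
the characterized system: RNA half-life ~2 min, cleavage characteristic
time ~6 min, reporter degradation characteristic time ~12 min, effective
signal dissociation constant ~1 mM.  The dynamics is set by cleavage and
reporter degradation; copy number (beta_R), K_RU, and the cleaved fraction
move only the stationary level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "CascadeParams",
    "SignalProfile",
    "Trajectory",
    "build_signal_profile",
    "simulate_cascade",
    "steady_state",
    "response_time",
    "single_cell_ensemble",
    "population_cv",
]


@dataclass(frozen=True)
class CascadeParams:
    """Rate constants of the cascade model (minutes / molecules / mM)."""

    beta_R: float = 10.0          # regazyme transcription rate, molecules/min (copy-number lumped)
    delta_R: float = math.log(2) / 2.0   # RNA degradation, min^-1 (2-min half-life)
    k_leak: float = 0.0           # basal cleavage, min^-1
    k_cat: float = 1.0 / 6.0      # maximal induced cleavage, min^-1 (~6-min characteristic time)
    K_s: float = 1.0              # effective signal dissociation constant, mM
    K_RU: float = 100.0           # riboregulator–5'UTR effective Kd, molecules
    alpha_G: float = 100.0        # maximal reporter production, a.u./min
    delta_G: float = 1.0 / 12.0   # reporter degradation, min^-1 (~12-min characteristic time)

    def __post_init__(self) -> None:
        for name in ("delta_R", "K_s", "K_RU", "alpha_G", "delta_G"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        # beta_R and k_cat may be zero (production off / dead ribozyme)
        for name in ("beta_R", "k_leak", "k_cat"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def cleavage_rate(self, s: float) -> float:
        return self.k_leak + self.k_cat * s / (self.K_s + s)


@dataclass(frozen=True)
class SignalProfile:
    """Piecewise-constant signal concentration versus time.

    ``breakpoints`` are the times at which the level changes; ``levels``
    has one more entry than ``breakpoints`` (level before the first break,
    between consecutive breaks, and after the last).  ``period`` > 0 makes
    the profile periodic.
    """

    breakpoints: tuple[float, ...]
    levels: tuple[float, ...]
    period: float = 0.0

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        lv = np.asarray(self.levels, dtype=float)
        if lv.size != bp.size + 1:
            raise ValueError("need len(levels) == len(breakpoints) + 1")
        if bp.size and ((np.diff(bp) <= 0).any() or (bp < 0).any()):
            raise ValueError("breakpoints must be non-negative and ascending")
        if (lv < 0).any():
            raise ValueError("signal levels must be non-negative")
        if self.period < 0:
            raise ValueError("period must be non-negative")

    def __call__(self, t: float) -> float:
        if t < 0:
            raise ValueError("signal profile defined for t >= 0")
        if self.period > 0:
            t = t % self.period
        return float(self.levels[np.searchsorted(self.breakpoints, t, side="right")])

    def breaks_in(self, t0: float, t1: float) -> list[float]:
        """Discontinuity times strictly inside (t0, t1)."""
        if self.period > 0:
            out = []
            k0 = math.floor(t0 / self.period)
            k1 = math.floor(t1 / self.period) + 1
            for k in range(k0, k1 + 1):
                for b in list(self.breakpoints) + [0.0]:
                    tb = k * self.period + b
                    if t0 < tb < t1:
                        out.append(tb)
            return sorted(set(out))
        return [b for b in self.breakpoints if t0 < b < t1]


def build_signal_profile(kind: str, **kw) -> SignalProfile:
    """Construct a step, pulse, or square-wave signal profile.

    step: ``level``, ``t_on`` (default 0)
    pulse: ``level``, ``t_on``, ``width``
    square_wave: ``level``, ``period``, ``duty`` (ON fraction, default 0.5)
    """
    if kind == "step":
        level, t_on = kw["level"], kw.get("t_on", 0.0)
        if t_on > 0:
            return SignalProfile((t_on,), (0.0, level))
        return SignalProfile((), (level,))
    if kind == "pulse":
        level, t_on, width = kw["level"], kw.get("t_on", 0.0), kw["width"]
        if width <= 0:
            raise ValueError("pulse width must be positive")
        if t_on > 0:
            return SignalProfile((t_on, t_on + width), (0.0, level, 0.0))
        return SignalProfile((width,), (level, 0.0))
    if kind == "square_wave":
        level, period, duty = kw["level"], kw["period"], kw.get("duty", 0.5)
        if period <= 0 or not (0 < duty < 1):
            raise ValueError("square wave needs period > 0 and duty in (0,1)")
        return SignalProfile((duty * period,), (level, 0.0), period=period)
    raise ValueError(f"unknown signal profile kind {kind!r}")


@dataclass
class Trajectory:
    """State trajectory on an ascending time grid (minutes)."""

    t: np.ndarray
    Ru: np.ndarray
    Ra: np.ndarray
    G: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("Ru", "Ra", "G"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.t.shape:
                raise ValueError(f"{name} shape does not match time grid")
            setattr(self, name, arr)
        if self.t.size and (np.diff(self.t) <= 0).any():
            raise ValueError("time grid must be strictly ascending")


def simulate_cascade(
    params: CascadeParams,
    profile: SignalProfile,
    t_grid,
    y0: tuple[float, float, float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the cascade ODEs over ``t_grid`` (stiff-safe LSODA).

    Integration restarts at every signal discontinuity so piecewise
    forcing is handled exactly.  ``y0`` defaults to the signal-free steady
    state of the RNA species with no reporter, i.e. a culture growing
    without inducer.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.size < 2 or (np.diff(t) <= 0).any():
        raise ValueError("t_grid must be ascending with at least two points")
    if y0 is None:
        ru0, ra0, _ = steady_state(params, 0.0)
        y0 = (ru0, ra0, 0.0)
    y = np.array(y0, dtype=float)
    if (y < 0).any():
        raise ValueError("initial state must be non-negative")

    def rhs(_t, state, k):
        ru, ra, g = state
        return (
            params.beta_R - (k + params.delta_R) * ru,
            k * ru - params.delta_R * ra,
            params.alpha_G * ra / (params.K_RU + ra) - params.delta_G * g,
        )

    out = np.empty((3, t.size))
    out[:, 0] = y
    segments = [t[0]] + profile.breaks_in(t[0], t[-1]) + [t[-1]]
    for a, b in zip(segments[:-1], segments[1:]):
        k = params.cleavage_rate(profile((a + b) / 2.0))
        mask = (t > a) & (t <= b)
        eval_pts = t[mask]
        pts = np.unique(np.append(eval_pts, b))  # always carry the state to b
        sol = solve_ivp(
            rhs, (a, b), y, method="LSODA", t_eval=pts,
            rtol=rtol, atol=atol, args=(k,),
        )
        if not sol.success:
            raise RuntimeError(f"cascade integration failed: {sol.message}")
        if eval_pts.size:
            out[:, mask] = sol.y[:, np.isin(pts, eval_pts)]
        y = sol.y[:, -1]
    ru, ra, g = np.clip(out, 0.0, None)
    return Trajectory(t, ru, ra, g)


def steady_state(params: CascadeParams, s: float) -> tuple[float, float, float]:
    """Closed-form fixed point (Ru*, Ra*, G*) at constant signal level s."""
    if s < 0:
        raise ValueError("signal level must be non-negative")
    k = params.cleavage_rate(s)
    ru = params.beta_R / (k + params.delta_R)
    ra = k * ru / params.delta_R
    g = params.alpha_G * ra / (params.K_RU + ra) / params.delta_G
    return (ru, ra, g)


def response_time(
    trajectory: Trajectory, criterion: float = 0.95
) -> float:
    """First time the reporter crosses ``criterion`` of its total change.

    The trajectory must have reached a plateau (the reporter varies by
    less than 1% of its total change over the final 5% of the grid);
    crossing is located by linear interpolation between grid points.
    """
    if not (0 < criterion < 1):
        raise ValueError("criterion must lie in (0,1)")
    g = trajectory.G
    t = trajectory.t
    g0, g1 = g[0], g[-1]
    change = g1 - g0
    if change == 0:
        raise ValueError("reporter does not change; response time undefined")
    tail = g[t >= t[0] + 0.95 * (t[-1] - t[0])]
    if tail.size >= 2 and np.ptp(tail) > 0.01 * abs(change):
        raise ValueError("trajectory has not reached a plateau")
    target = g0 + criterion * change
    rel = (g - g0) / change  # rising or falling both map to [0,1]
    crossed = np.nonzero(rel >= criterion)[0]
    if crossed.size == 0:
        raise ValueError("reporter never crosses the criterion")
    i = crossed[0]
    if i == 0:
        return float(t[0])
    frac = (target - g[i - 1]) / (g[i] - g[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


#: parameters treated as extrinsically variable across cells by default
DEFAULT_NOISY_PARAMS = ("beta_R", "k_cat", "alpha_G")


def single_cell_ensemble(
    params: CascadeParams,
    profile: SignalProfile,
    t_grid,
    n_cells: int,
    extrinsic_cv: float,
    rng: np.random.Generator | int | None = None,
    noisy_params: tuple[str, ...] = DEFAULT_NOISY_PARAMS,
) -> list[Trajectory]:
    """Simulate cells whose rates vary lognormally around the nominal values.

    Each selected rate is multiplied, per cell, by a lognormal factor with
    mean 1 and coefficient of variation ``extrinsic_cv``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if extrinsic_cv < 0:
        raise ValueError("extrinsic_cv must be non-negative")
    rng = np.random.default_rng(rng)
    sigma2 = math.log(1.0 + extrinsic_cv**2)
    sigma = math.sqrt(sigma2)
    mu = -sigma2 / 2.0  # mean-one multiplier
    trajectories = []
    for _ in range(n_cells):
        if extrinsic_cv == 0:
            cell = params
        else:
            factors = {
                name: float(np.exp(mu + sigma * rng.standard_normal()))
                for name in noisy_params
            }
            cell = replace(
                params, **{k: getattr(params, k) * v for k, v in factors.items()}
            )
        trajectories.append(simulate_cascade(cell, profile, t_grid))
    return trajectories


def population_cv(ensemble: list[Trajectory], window: tuple[float, float]) -> float:
    """CV (sd/mean) of per-cell time-averaged reporter over an ON-state window."""
    a, b = window
    if not ensemble:
        raise ValueError("empty ensemble")
    if a >= b:
        raise ValueError("window must have positive width")
    means = []
    for traj in ensemble:
        mask = (traj.t >= a) & (traj.t <= b)
        if not mask.any():
            raise ValueError("window outside the simulated range")
        means.append(float(np.mean(traj.G[mask])))
    means = np.asarray(means)
    if means.mean() == 0:
        raise ValueError("mean reporter level is zero in the window")
    if means.size == 1:
        return 0.0
    return float(np.std(means, ddof=1) / np.mean(means))
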