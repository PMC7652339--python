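"""Per-well kinetic readouts for imaging-based killing/proliferation co-culture assays.

From raw well time series (live effector counts, red dead-cell pixel area,
phase-contrast occupied pixel area) this module derives, on a common 6-hour
grid anchored at the 2-hour settling scan:

=================  ==============================================================
P(t, c)            fold proliferation, E_live(t, c) / E_live(t0 = 2 h, c)
T_dead(t, c)       total death, 100% x red pixel area / phase pixel area
K(t, c)            specific killing, T_dead(t, c) / T_dead(t, 0)
S(t, c)            per-T-cell specific killing,
                   [T_dead(t, c)/E_live(t-6, c)] / [T_dead(t, 0)/E_live(t-6, 0)]
P'(t, c)           proliferation rate, 4 x [E(t) - E(t-6)] / E(t-6)  (per day)
K'(t, c)           kill rate, [K(t) - K(t-6)] / E_live(t-6) / 6 h
=================  ==============================================================

The 6-hour lag in S, P' and K' reflects that target death observed at t is
attributed to the effectors present 6 hours earlier. Normalisation to the
0-dose control removes nonspecific/allo-reactive killing; by construction
K(t, 0) = 1, S(t, 0) = 1 and K'(t, 0) = 0 identically, and P(t0) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

T0_HOURS = 2.0  # settling time before the first usable scan
GRID_STEP_HOURS = 6.0


class KineticsError(ValueError):
    pass


class MissingControlError(KineticsError):
    """A (construct, E:T) group lacks its mandatory 0-dose control well."""


@dataclass(frozen=True)
class Flag:
    """A data-quality annotation raised during kinetics processing."""

    scope: str        # e.g. well id or "construct @ E:T" group label
    code: str         # machine-readable, e.g. "zero_floor_clamp"
    time_h: Optional[float]
    detail: str

    def __str__(self) -> str:  # appears verbatim in reports
        at = f" t={self.time_h:g}h" if self.time_h is not None else ""
        return f"[{self.code}] {self.scope}{at}: {self.detail}"


@dataclass
class WellTimeSeries:
    """Raw per-well measurements over time.

    ``t`` must be strictly increasing and start at the 2 h settling scan;
    channels must share its length. ``e_live`` is the live (green-positive,
    red-negative) effector count; ``red_px``/``phase_px`` are pixel areas.
    """

    well_id: str
    construct: str
    et_ratio: float
    concentration: float  # molar
    t: np.ndarray
    e_live: np.ndarray
    red_px: np.ndarray
    phase_px: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.e_live = np.asarray(self.e_live, dtype=float)
        self.red_px = np.asarray(self.red_px, dtype=float)
        self.phase_px = np.asarray(self.phase_px, dtype=float)
        n = len(self.t)
        if any(len(a) != n for a in (self.e_live, self.red_px, self.phase_px)):
            raise KineticsError(f"well {self.well_id}: channel lengths differ")
        if n < 2:
            raise KineticsError(f"well {self.well_id}: need at least 2 time points")
        if not np.all(np.diff(self.t) > 0):
            raise KineticsError(f"well {self.well_id}: time must be strictly increasing")
        if abs(self.t[0] - T0_HOURS) > 1e-9:
            raise KineticsError(
                f"well {self.well_id}: series must start at the t0 = {T0_HOURS:g} h settling scan "
                f"(got t[0] = {self.t[0]:g} h)")
        for name, a in (("e_live", self.e_live), ("red_px", self.red_px),
                        ("phase_px", self.phase_px)):
            if not np.all(np.isfinite(a)) or np.any(a < 0):
                raise KineticsError(f"well {self.well_id}: {name} must be finite and >= 0")
        if self.et_ratio <= 0:
            raise KineticsError(f"well {self.well_id}: et_ratio must be > 0")
        if self.concentration < 0:
            raise KineticsError(f"well {self.well_id}: concentration must be >= 0")


def resample_to_grid(series: WellTimeSeries, step: float = GRID_STEP_HOURS) -> WellTimeSeries:
    """Linearly interpolate a well series onto the t = 2, 2+step, ... grid.

    Native samples that coincide with grid times are preserved exactly.
    The native cadence must not be coarser than the grid step.
    """
    t = series.t
    if t[-1] - t[0] < step:
        raise KineticsError(
            f"well {series.well_id}: series spans less than one grid step ({step:g} h)")
    if np.max(np.diff(t)) > step + 1e-9:
        raise KineticsError(
            f"well {series.well_id}: native cadence coarser than the {step:g} h grid")
    grid = T0_HOURS + step * np.arange(int(np.floor((t[-1] - T0_HOURS) / step + 1e-9)) + 1)
    return WellTimeSeries(
        well_id=series.well_id, construct=series.construct, et_ratio=series.et_ratio,
        concentration=series.concentration, t=grid,
        e_live=np.interp(grid, t, series.e_live),
        red_px=np.interp(grid, t, series.red_px),
        phase_px=np.interp(grid, t, series.phase_px),
    )


# ---------------------------------------------------------------------------
# the six readouts, each on already-gridded channel arrays
# ---------------------------------------------------------------------------

def fold_proliferation(e_live: np.ndarray) -> np.ndarray:
    """P(t) = E_live(t) / E_live(t0). Requires a positive count at t0."""
    e_live = np.asarray(e_live, dtype=float)
    if e_live[0] <= 0:
        raise KineticsError("E_live at t0 is zero: well unusable for fold proliferation")
    return e_live / e_live[0]


def death_fraction(red_px: np.ndarray, phase_px: np.ndarray) -> np.ndarray:
    """T_dead(t) = 100% x red_px / phase_px; NaN where phase_px = 0 (flagged upstream)."""
    red_px = np.asarray(red_px, dtype=float)
    phase_px = np.asarray(phase_px, dtype=float)
    out = np.full_like(red_px, np.nan)
    ok = phase_px > 0
    out[ok] = red_px[ok] / phase_px[ok] * 100.0
    return out


def specific_killing(td_c: np.ndarray, td_0: np.ndarray,
                     floor: Optional[np.ndarray] = None) -> tuple[np.ndarray, np.ndarray]:
    """K(t) = T_dead(t, c) / T_dead(t, 0), with a one-pixel floor on the control.

    ``floor`` is the death fraction equivalent to a single red pixel in the
    control well (100/phase_px); control values below it are clamped up so a
    spotless control cannot blow up the ratio. Returns (K, clamped mask).
    """
    td_c = np.asarray(td_c, dtype=float)
    td_0 = np.asarray(td_0, dtype=float)
    if floor is None:
        floor = np.zeros_like(td_0)
    denom = td_0.copy()
    clamped = denom < floor
    denom[clamped] = floor[clamped]
    k = np.where(denom > 0, td_c / np.where(denom > 0, denom, 1.0), np.nan)
    return k, clamped


def killing_per_tcell(td_c: np.ndarray, e_c: np.ndarray,
                      td_0: np.ndarray, e_0: np.ndarray,
                      lag_steps: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """S(t) = [T_dead(t,c)/E_live(t-lag,c)] / [T_dead(t,0)/E_live(t-lag,0)].

    Effector counts are floored at 1 cell (flagged). The first ``lag_steps``
    grid points are NaN (no effectors observable one lag earlier). Returns
    (S, clamped mask).
    """
    td_c, e_c = np.asarray(td_c, float), np.asarray(e_c, float)
    td_0, e_0 = np.asarray(td_0, float), np.asarray(e_0, float)
    n = len(td_c)
    s = np.full(n, np.nan)
    clamped = np.zeros(n, dtype=bool)
    for i in range(lag_steps, n):
        ec, e0 = e_c[i - lag_steps], e_0[i - lag_steps]
        if ec < 1 or e0 < 1:
            clamped[i] = True
            ec, e0 = max(ec, 1.0), max(e0, 1.0)
        num = td_c[i] / ec
        den = td_0[i] / e0
        s[i] = num / den if den > 0 else np.nan
    return s, clamped


def proliferation_rate(e_live: np.ndarray, lag_steps: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """P'(t) = 4 x [E(t) - E(t-6)] / E(t-6), per day (fraction, not percent).

    The x4 converts the 6-hour difference to a daily rate. Negative rates are
    reported as-is. Zero denominators yield NaN and a flag. Returns
    (rate, flagged mask).
    """
    e = np.asarray(e_live, dtype=float)
    n = len(e)
    rate = np.full(n, np.nan)
    flagged = np.zeros(n, dtype=bool)
    for i in range(lag_steps, n):
        if e[i - lag_steps] > 0:
            rate[i] = (e[i] - e[i - lag_steps]) / e[i - lag_steps] * 4.0
        else:
            flagged[i] = True
    return rate, flagged


def kill_rate(k: np.ndarray, e_live: np.ndarray, lag_steps: int = 1,
              step: float = GRID_STEP_HOURS) -> tuple[np.ndarray, np.ndarray]:
    """K'(t) = [K(t) - K(t-6)] / E_live(t-6) / 6 h  (per T cell per hour).

    Effector counts floored at 1 cell (flagged). Returns (rate, clamped mask).
    """
    k = np.asarray(k, dtype=float)
    e = np.asarray(e_live, dtype=float)
    n = len(k)
    rate = np.full(n, np.nan)
    clamped = np.zeros(n, dtype=bool)
    for i in range(lag_steps, n):
        denom = e[i - lag_steps]
        if denom < 1:
            clamped[i] = True
            denom = 1.0
        rate[i] = (k[i] - k[i - lag_steps]) / denom / step
    return rate, clamped


# ---------------------------------------------------------------------------
# plate-level orchestration
# ---------------------------------------------------------------------------

@dataclass
class KineticProfile:
    """Derived curves for one (construct, E:T) group on the 6-hour grid.

    2-D arrays are indexed [concentration, time]. ``p_prime_pct_day`` carries
    P' scaled to %/day (the reporting unit); ``kill_rate`` is per T cell per
    hour. ``e_live`` holds the replicate-averaged effector counts used in the
    normalisations.
    """

    construct: str
    et_ratio: float
    concentrations: np.ndarray     # molar, ascending, includes 0
    t_grid: np.ndarray             # hours
    p_fold: np.ndarray
    t_dead_pct: np.ndarray
    k_specific: np.ndarray
    s_per_tcell: np.ndarray
    p_prime_pct_day: np.ndarray
    k_prime: np.ndarray
    e_live: np.ndarray
    flags: list[Flag] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one row per concentration x grid time."""
        rows = []
        flag_codes: dict[float, set[str]] = {}
        for f in self.flags:
            if f.time_h is not None:
                flag_codes.setdefault(f.time_h, set()).add(f.code)
        for i, c in enumerate(self.concentrations):
            for j, t in enumerate(self.t_grid):
                rows.append({
                    "construct": self.construct,
                    "et_ratio": self.et_ratio,
                    "concentration_m": c,
                    "concentration_um": c * 1e6,
                    "time_h": t,
                    "p_fold": self.p_fold[i, j],
                    "t_dead_pct": self.t_dead_pct[i, j],
                    "k_specific": self.k_specific[i, j],
                    "s_per_tcell": self.s_per_tcell[i, j],
                    "p_prime_pct_day": self.p_prime_pct_day[i, j],
                    "k_prime_per_tcell_hr": self.k_prime[i, j],
                    "flags": ";".join(sorted(flag_codes.get(t, ()))),
                })
        return pd.DataFrame(rows)


def _group_label(construct: str, et_ratio: float) -> str:
    return f"{construct} @ E:T {et_ratio:g}"


def build_profiles(wells: Sequence[WellTimeSeries],
                   grid_step: float = GRID_STEP_HOURS,
                   lag: float = GRID_STEP_HOURS) -> list[KineticProfile]:
    """Compute all six readouts for every (construct, E:T) group on a plate.

    Replicate wells at the same (construct, E:T, concentration) are averaged
    after per-well computation of P and T_dead (and of the raw effector
    counts); the dose-normalised quantities (K, S) then use the group's
    averaged 0-dose control curves. Every group must include a 0-dose control.
    """
    if lag % grid_step:
        raise KineticsError("lag must be an integer multiple of grid_step")
    lag_steps = int(round(lag / grid_step))

    groups: dict[tuple[str, float], list[WellTimeSeries]] = {}
    for w in wells:
        groups.setdefault((w.construct, w.et_ratio), []).append(w)

    missing = [_group_label(c, r) for (c, r), ws in groups.items()
               if not any(w.concentration == 0 for w in ws)]
    if missing:
        raise MissingControlError(
            "groups lack the mandatory 0-dose control well: " + ", ".join(sorted(missing)))

    profiles = []
    for (construct, et_ratio), ws in sorted(groups.items()):
        label = _group_label(construct, et_ratio)
        flags: list[Flag] = []
        gridded = [resample_to_grid(w, grid_step) for w in ws]
        n_t = min(len(g.t) for g in gridded)
        t_grid = gridded[0].t[:n_t]

        concs = np.array(sorted({g.concentration for g in gridded}))
        p_mean = np.full((len(concs), n_t), np.nan)
        td_mean = np.full((len(concs), n_t), np.nan)
        e_mean = np.full((len(concs), n_t), np.nan)
        phase_mean = np.full((len(concs), n_t), np.nan)

        for i, c in enumerate(concs):
            reps = [g for g in gridded if g.concentration == c]
            p_curves = []
            for g in reps:
                try:
                    p_curves.append(fold_proliferation(g.e_live[:n_t]))
                except KineticsError:
                    flags.append(Flag(g.well_id, "zero_t0_count", float(t_grid[0]),
                                      "E_live(t0) = 0; well excluded from P"))
            td_curves = []
            for g in reps:
                td = death_fraction(g.red_px[:n_t], g.phase_px[:n_t])
                for j in np.flatnonzero(~np.isfinite(td)):
                    flags.append(Flag(g.well_id, "zero_phase_area", float(t_grid[j]),
                                      "phase_px = 0; time point excluded"))
                td_curves.append(td)
            if p_curves:
                p_mean[i] = np.mean(p_curves, axis=0)
            with np.errstate(invalid="ignore"):
                td_mean[i] = np.nanmean(td_curves, axis=0)
            e_mean[i] = np.mean([g.e_live[:n_t] for g in reps], axis=0)
            phase_mean[i] = np.mean([g.phase_px[:n_t] for g in reps], axis=0)

        i0 = int(np.flatnonzero(concs == 0)[0])
        e0 = e_mean[i0]
        # One-pixel floor: the death fraction a single red pixel would produce.
        # The control curve itself is floored, so the c = 0 row self-normalises
        # to exactly 1 even when clamped.
        with np.errstate(divide="ignore"):
            floor = np.where(phase_mean[i0] > 0, 100.0 / phase_mean[i0], 0.0)
        control_clamped = td_mean[i0] < floor
        for j in np.flatnonzero(control_clamped):
            flags.append(Flag(label, "zero_floor_clamp", float(t_grid[j]),
                              "control T_dead below one-pixel floor; clamped"))
        td_mean[i0] = np.maximum(td_mean[i0], floor)
        td0 = td_mean[i0]

        k_arr = np.full_like(p_mean, np.nan)
        s_arr = np.full_like(p_mean, np.nan)
        pp_arr = np.full_like(p_mean, np.nan)
        kp_arr = np.full_like(p_mean, np.nan)
        for i, c in enumerate(concs):
            k_arr[i], _ = specific_killing(td_mean[i], td0)
            s_arr[i], s_clamped = killing_per_tcell(td_mean[i], e_mean[i], td0, e0,
                                                    lag_steps=lag_steps)
            for j in np.flatnonzero(s_clamped):
                flags.append(Flag(label, "effector_floor_clamp", float(t_grid[j]),
                                  f"E_live(t-{lag:g}h) < 1 clamped at c={c:g} M"))
            pp, pp_flagged = proliferation_rate(e_mean[i], lag_steps=lag_steps)
            pp_arr[i] = pp * 100.0  # report %/day
            for j in np.flatnonzero(pp_flagged):
                flags.append(Flag(label, "zero_effector_denominator", float(t_grid[j]),
                                  f"E_live(t-{lag:g}h) = 0 at c={c:g} M; P' undefined"))
            kp_arr[i], kp_clamped = kill_rate(k_arr[i], e_mean[i], lag_steps=lag_steps,
                                              step=grid_step)
            for j in np.flatnonzero(kp_clamped):
                flags.append(Flag(label, "effector_floor_clamp", float(t_grid[j]),
                                  f"E_live(t-{lag:g}h) < 1 clamped in K' at c={c:g} M"))

        profiles.append(KineticProfile(
            construct=construct, et_ratio=et_ratio, concentrations=concs, t_grid=t_grid,
            p_fold=p_mean, t_dead_pct=td_mean, k_specific=k_arr, s_per_tcell=s_arr,
            p_prime_pct_day=pp_arr, k_prime=kp_arr, e_live=e_mean, flags=flags))
    return profiles


def profiles_to_frame(profiles: Sequence[KineticProfile]) -> pd.DataFrame:
    """Concatenate tidy tables for a set of profiles (the profiles CSV schema)."""
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)
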