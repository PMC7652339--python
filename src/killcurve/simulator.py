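"""Stochastic co-culture simulator: dose-dependent killing and proliferation.

A discrete-time birth-death model of an effector/target co-culture well,
emitting the same three measurements the imaging assay produces (live
effector count, red dead-cell pixel area, phase-contrast pixel area) plus the
latent ground truth, for end-to-end recovery tests.

Model per scan interval dt (binomial thinning with exact exponential hazards):

* each live target dies with probability
  ``1 - exp(-(h0 + hmax * hill_k(c) * rho_E) * dt)`` where
  ``rho_E = E/(E+T)`` is the effector density. Antigen-specific killing
  requires effector engagement and saturates with effector density; the
  nonspecific hazard ``h0`` models spontaneous/background target death and is
  effector-independent, so the 0-dose control reads the same baseline at
  every E:T ratio.
* each live effector divides with probability
  ``1 - exp(-(g0 + gmax * hill_p(c)) * (1 - gamma * kill_fraction) * dt/24)``
  where ``kill_fraction`` is the per-target death probability of the current
  step while targets remain (0 once targets are extinct): cytotoxic
  engagement transiently suppresses division.
* live targets regrow logistically toward the well carrying capacity.

Emitted measurements: ``e_live`` = effector count (Poisson-resampled when
configured), ``red_px`` = red area per dead cell x accumulated red signal
(persistent by default; exponential clearance optional), ``phase_px`` = phase
area per target x (live + dead targets). The first emitted scan is at
t0 = 2 h, after cell settling; no dynamics are applied before it.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import SimulationConfig
from .kinetics import T0_HOURS, WellTimeSeries

if TYPE_CHECKING:  # pragma: no cover
    from .platemap import PlateMap


class SimulationError(ValueError):
    pass


def hill_response(c: float, ec50: float, slope: float) -> float:
    """Hill activation fraction c^s / (c^s + ec50^s), in [0, 1].

    0 at c = 0, 0.5 at c = ec50, -> 1 as c -> inf. Computed on the log scale
    (a logistic in log-concentration) so extreme c/ec50 ratios cannot
    overflow.
    """
    for name, v in (("c", c), ("ec50", ec50), ("slope", slope)):
        if not np.isfinite(v):
            raise SimulationError(f"hill_response: {name} must be finite, got {v!r}")
    if ec50 <= 0 or slope <= 0:
        raise SimulationError("hill_response: ec50 and slope must be > 0")
    if c < 0:
        raise SimulationError("hill_response: concentration must be >= 0")
    if c == 0:
        return 0.0
    return float(expit(slope * (np.log(c) - np.log(ec50))))


@dataclass
class LatentTrajectory:
    """Ground-truth per-well state at every emitted scan time."""

    t: np.ndarray               # hours
    targets_live: np.ndarray    # int counts
    targets_dead_cum: np.ndarray
    effectors: np.ndarray
    target_births_cum: np.ndarray

    def to_dict(self) -> dict:
        return {k: np.asarray(v).tolist() for k, v in vars(self).items()}


def simulate_well(config: SimulationConfig, concentration: float, et_ratio: float,
                  well_seed, well_id: str = "W01",
                  construct: str = "sim") -> tuple[WellTimeSeries, LatentTrajectory]:
    """Simulate one co-culture well; returns the emitted series and latent truth.

    ``well_seed`` may be an int or a numpy SeedSequence. Extinction of either
    population is a valid state: the series continues with zeros/last values.
    """
    if et_ratio <= 0:
        raise SimulationError("et_ratio must be > 0")
    if not any(np.isclose(concentration, c, rtol=1e-9, atol=0.0) or concentration == c
               for c in config.concentrations):
        raise SimulationError(
            f"concentration {concentration!r} not in the configured list")

    rng = np.random.default_rng(well_seed)
    dt = config.scan_interval
    times = T0_HOURS + dt * np.arange(int(round((config.horizon - T0_HOURS) / dt)) + 1)

    h_kill = config.kill_max_hazard * hill_response(
        concentration, config.kill_EC50, config.hill_slope_kill)
    g_div = (config.prolif_baseline + config.prolif_max_rate * hill_response(
        concentration, config.prolif_EC50, config.hill_slope_prolif))

    targets = config.target_seed_count
    effectors = int(round(config.target_seed_count * et_ratio))
    dead_cum = 0
    births_cum = 0
    red_signal = 0.0  # dead-cell equivalents, with optional clearance
    decay = np.exp(-config.red_decay_per_hour * dt)

    n = len(times)
    lat_t = np.zeros(n, dtype=np.int64)
    lat_d = np.zeros(n, dtype=np.int64)
    lat_e = np.zeros(n, dtype=np.int64)
    lat_b = np.zeros(n, dtype=np.int64)
    e_meas = np.zeros(n, dtype=np.int64)
    red_px = np.zeros(n)
    phase_px = np.zeros(n)

    for i in range(n):
        lat_t[i], lat_d[i], lat_e[i], lat_b[i] = targets, dead_cum, effectors, births_cum
        e_meas[i] = rng.poisson(effectors) if config.count_noise == "poisson" else effectors
        red_px[i] = config.red_area_per_dead_cell * red_signal
        phase_px[i] = config.phase_area_per_target * (targets + dead_cum)

        if i == n - 1:
            break

        total = targets + effectors
        rho_e = effectors / total if total > 0 else 0.0
        hazard = config.nonspecific_hazard + h_kill * rho_e
        p_die = 1.0 - np.exp(-hazard * dt)
        deaths = rng.binomial(targets, p_die) if targets > 0 else 0
        kill_fraction = p_die if targets > 0 else 0.0

        div_rate = g_div * max(0.0, 1.0 - config.coupling_strength * kill_fraction)
        p_div = 1.0 - np.exp(-div_rate * dt / 24.0)
        divisions = rng.binomial(effectors, p_div) if effectors > 0 else 0

        growth = config.target_growth_rate * max(
            0.0, 1.0 - targets / config.well_carrying_capacity)
        p_grow = 1.0 - np.exp(-growth * dt / 24.0)
        target_births = rng.binomial(targets, p_grow) if targets > 0 else 0

        targets = targets - deaths + target_births
        dead_cum += deaths
        births_cum += target_births
        effectors += divisions
        red_signal = red_signal * decay + deaths

    series = WellTimeSeries(
        well_id=well_id, construct=construct, et_ratio=et_ratio,
        concentration=concentration, t=times,
        e_live=e_meas.astype(float), red_px=red_px, phase_px=phase_px)
    latent = LatentTrajectory(t=times, targets_live=lat_t, targets_dead_cum=lat_d,
                              effectors=lat_e, target_births_cum=lat_b)
    return series, latent


@dataclass
class SimulationTruth:
    """A simulated plate: emitted series paired with latent ground truth."""

    config: SimulationConfig
    series: dict[str, WellTimeSeries]          # well_id -> emitted measurements
    latent: dict[str, LatentTrajectory]        # well_id -> ground truth
    construct_configs: dict[str, SimulationConfig]

    @property
    def wells(self) -> list[WellTimeSeries]:
        return list(self.series.values())

    def to_wells_frame(self) -> pd.DataFrame:
        """Per-well CSV schema: well_id, time_h, e_live, red_px, phase_px (+ layout)."""
        rows = []
        for wid, s in self.series.items():
            for j in range(len(s.t)):
                rows.append({"well_id": wid, "construct": s.construct,
                             "et_ratio": s.et_ratio, "concentration_m": s.concentration,
                             "time_h": s.t[j], "e_live": s.e_live[j],
                             "red_px": s.red_px[j], "phase_px": s.phase_px[j]})
        return pd.DataFrame(rows)

    def save_truth(self, path: str | Path) -> None:
        """Ground-truth JSON sidecar: generative parameters + latent trajectories."""
        payload = {
            "config": self.config.model_dump(mode="json"),
            "construct_configs": {k: v.model_dump(mode="json")
                                  for k, v in self.construct_configs.items()},
            "latent": {wid: lat.to_dict() for wid, lat in self.latent.items()},
        }
        Path(path).write_text(json.dumps(payload))


def well_seed_sequence(rng_seed: int, well_id: str) -> np.random.SeedSequence:
    """Reproducible per-well seed, independent of well iteration order."""
    return np.random.SeedSequence([int(rng_seed), zlib.crc32(well_id.encode())])


def simulate_plate(config: SimulationConfig, plate: "PlateMap",
                   construct_configs: Optional[dict[str, SimulationConfig]] = None,
                   ) -> SimulationTruth:
    """Simulate every well of a plate map; bit-identical for identical rng_seed.

    ``construct_configs`` optionally maps construct names to per-construct
    parameter sets (e.g. different kill EC50s); unlisted constructs use
    ``config``. Every well's concentration and E:T ratio must appear in the
    lists of the config that simulates it.
    """
    construct_configs = dict(construct_configs or {})
    bad: list[str] = []
    for row in plate.frame.itertuples():
        cfg = construct_configs.get(row.construct, config)
        if not any(row.concentration_m == c for c in cfg.concentrations):
            bad.append(f"{row.well_id} (concentration {row.concentration_m:g} M "
                       f"not in config for {row.construct!r})")
        elif not any(np.isclose(row.et_ratio, r, rtol=1e-9)
                     for r in cfg.effector_to_target_ratios):
            bad.append(f"{row.well_id} (E:T {row.et_ratio:g} not in config "
                       f"for {row.construct!r})")
    if bad:
        raise SimulationError("plate/config mismatch: " + "; ".join(bad))

    series: dict[str, WellTimeSeries] = {}
    latent: dict[str, LatentTrajectory] = {}
    for row in plate.frame.itertuples():
        cfg = construct_configs.get(row.construct, config)
        s, lat = simulate_well(
            cfg, row.concentration_m, row.et_ratio,
            well_seed=well_seed_sequence(config.rng_seed, row.well_id),
            well_id=row.well_id, construct=row.construct)
        series[row.well_id] = s
        latent[row.well_id] = lat
    return SimulationTruth(config=config, series=series, latent=latent,
                           construct_configs=construct_configs)
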