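"""Run orchestration: simulate / render+quantify / kinetics / dose-response / report.

Three entry modes decouple the stages:

* ``from_simulation`` — stochastic co-culture simulation emits well series
  directly (plus a ground-truth sidecar).
* ``from_images`` — the simulation's latent state is rendered into synthetic
  three-channel fields (a configurable fraction of each well's cells, as a
  microscope sees part of a well) and re-quantified by the segmenter; counts
  are on the field scale, which cancels in every ratio-based readout.
* ``from_counts`` — pre-quantified per-well CSV plus a plate map, for users
  with their own instrument exports.

Every run writes the well series CSV, the kinetic-profile CSV, per-group fit
JSONs, the EC50/Emax summary (CSV + aligned text), a log, and a manifest;
identical config + seed reproduce byte-identical tabular outputs.
"""

from __future__ import annotations

import json
import logging
import platform
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import (AnalysisParams, PipelineConfig, SimulationConfig, config_hash,
                     load_config)
from .doseresponse import (DoseResponseFit, fit_profile, summarize, summary_text)
from .imaging import quantify_stack, render_frame
from .kinetics import KineticProfile, WellTimeSeries, build_profiles, profiles_to_frame
from .platemap import PlateMap, build_platemap, read_platemap
from .simulator import SimulationTruth, simulate_plate

MODES = ("from_simulation", "from_images", "from_counts")
log = logging.getLogger("killcurve")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, well: Optional[str] = None):
        self.stage, self.well = stage, well
        ctx = f" [well {well}]" if well else ""
        super().__init__(f"stage {stage!r}{ctx}: {message}")


@dataclass
class RunManifest:
    """Provenance for one pipeline run; same manifest => same outputs."""

    mode: str
    seed: int
    config_sha256: str
    package_version: str
    library_versions: dict[str, str]
    inputs: dict[str, str]
    outputs: list[str] = field(default_factory=list)
    flag_counts: dict[str, int] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _library_versions() -> dict[str, str]:
    import scipy
    import skimage

    return {"python": platform.python_version(), "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "scikit-image": skimage.__version__}


def _construct_configs(config: PipelineConfig, seed: int) -> tuple[SimulationConfig,
                                                                   dict[str, SimulationConfig]]:
    base = config.simulation.model_copy(update={"rng_seed": seed})
    per_construct = {}
    for name, overrides in config.plate.constructs.items():
        per_construct[name] = base.model_copy(update=overrides) if overrides else base
    return base, per_construct


def build_plate_for_config(config: PipelineConfig, seed: int) -> PlateMap:
    base, per_construct = _construct_configs(config, seed)
    return build_platemap(
        constructs=sorted(per_construct),
        et_ratios=sorted(base.effector_to_target_ratios, reverse=True),
        concentrations_m=list(base.concentrations),
        replicates=config.plate.replicates,
        plate_format=config.plate.plate_format,
        provenance="generated from pipeline config")


def wells_to_frame(wells: Sequence[WellTimeSeries]) -> pd.DataFrame:
    rows = []
    for s in wells:
        for j in range(len(s.t)):
            rows.append({"well_id": s.well_id, "construct": s.construct,
                         "et_ratio": s.et_ratio, "concentration_m": s.concentration,
                         "time_h": s.t[j], "e_live": s.e_live[j],
                         "red_px": s.red_px[j], "phase_px": s.phase_px[j]})
    return pd.DataFrame(rows)


def read_wells_csv(path: str | Path, plate: Optional[PlateMap] = None) -> list[WellTimeSeries]:
    """Load well time series from CSV.

    The CSV needs well_id, time_h, e_live, red_px, phase_px; layout columns
    (construct, et_ratio, concentration_m or concentration_um) may be inline
    or joined from a plate map.
    """
    df = pd.read_csv(path)
    required = {"well_id", "time_h", "e_live", "red_px", "phase_px"}
    missing = required - set(df.columns)
    if missing:
        raise PipelineError("read_counts", f"wells CSV missing columns {sorted(missing)}")
    if "concentration_m" not in df.columns and "concentration_um" in df.columns:
        df["concentration_m"] = df["concentration_um"] * 1e-6
    layout_inline = {"construct", "et_ratio", "concentration_m"} <= set(df.columns)
    if not layout_inline:
        if plate is None:
            raise PipelineError("read_counts",
                                "wells CSV lacks layout columns and no plate map given")
        df = df.merge(plate.frame[["well_id", "construct", "et_ratio", "concentration_m"]],
                      on="well_id", how="left", validate="many_to_one")
        unmatched = df.loc[df["construct"].isna(), "well_id"].unique()
        if len(unmatched):
            raise PipelineError("read_counts",
                                f"wells absent from plate map: {sorted(unmatched)}")
    wells = []
    for wid, grp in df.groupby("well_id", sort=True):
        grp = grp.sort_values("time_h")
        wells.append(WellTimeSeries(
            well_id=str(wid), construct=str(grp["construct"].iloc[0]),
            et_ratio=float(grp["et_ratio"].iloc[0]),
            concentration=float(grp["concentration_m"].iloc[0]),
            t=grp["time_h"].to_numpy(), e_live=grp["e_live"].to_numpy(),
            red_px=grp["red_px"].to_numpy(), phase_px=grp["phase_px"].to_numpy()))
    return wells


def render_and_quantify_plate(truth: SimulationTruth, config: PipelineConfig,
                              seed: int) -> list[WellTimeSeries]:
    """Render each well's latent state into frames and re-quantify them.

    The rendered field holds ``field_fraction`` of the well's cells
    (deterministic rounding); frames may be strided to every Nth scan.
    """
    frac = config.imaging_mode.field_fraction
    stride = config.imaging_mode.frame_stride
    wells = []
    for wid, lat in truth.latent.items():
        src = truth.series[wid]
        frames = []
        idx = list(range(0, len(lat.t), stride))
        if idx[-1] != len(lat.t) - 1:
            idx.append(len(lat.t) - 1)
        for j in idx:
            n_eff = int(round(lat.effectors[j] * frac))
            n_live = int(round(lat.targets_live[j] * frac))
            n_dead = int(round(lat.targets_dead_cum[j] * frac))
            seed_j = np.random.SeedSequence(
                [seed, zlib.crc32(wid.encode()), j, 0x5eed])
            try:
                rendered = render_frame(n_eff, n_live, n_dead,
                                        params=config.rendering, seed=seed_j,
                                        time_h=float(lat.t[j]), well_id=wid)
            except Exception as exc:
                raise PipelineError("render", str(exc), well=wid) from exc
            frames.append(rendered.frame)
        try:
            wells.append(quantify_stack(frames, config.segmentation,
                                        construct=src.construct, et_ratio=src.et_ratio,
                                        concentration=src.concentration))
        except Exception as exc:
            raise PipelineError("quantify", str(exc), well=wid) from exc
    return wells


def analyze_wells(wells: Sequence[WellTimeSeries], params: AnalysisParams,
                  ) -> tuple[list[KineticProfile], list[DoseResponseFit], pd.DataFrame]:
    """Kinetics + dose-response for a set of well series."""
    profiles = build_profiles(wells, grid_step=params.grid_step, lag=params.lag)
    fits: list[DoseResponseFit] = []
    for prof in profiles:
        fits.extend(fit_profile(prof, params))
    return profiles, fits, summarize(fits)


def _setup_logging(out_dir: Path, level: str) -> None:
    log.setLevel(getattr(logging, level.upper(), logging.INFO))
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    fh = logging.FileHandler(out_dir / "run.log", mode="w")
    fh.setFormatter(fmt)
    sh = logging.StreamHandler()
    sh.setFormatter(fmt)
    log.addHandler(fh)
    log.addHandler(sh)


def run_pipeline(config: PipelineConfig | str | Path, mode: str, out_dir: str | Path,
                 seed: Optional[int] = None, platemap_path: Optional[str | Path] = None,
                 wells_path: Optional[str | Path] = None,
                 log_level: str = "INFO") -> Path:
    """Execute one reproducible run; returns the output directory.

    ``seed`` overrides the simulation config's rng_seed. ``from_counts``
    requires ``wells_path`` (and ``platemap_path`` unless the CSV carries its
    own layout columns).
    """
    if mode not in MODES:
        raise PipelineError("setup", f"unknown mode {mode!r}; expected one of {MODES}")
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, log_level)
    run_seed = int(seed if seed is not None else config.simulation.rng_seed)
    manifest = RunManifest(mode=mode, seed=run_seed, config_sha256=config_hash(config),
                           package_version=__version__,
                           library_versions=_library_versions(),
                           inputs={"platemap": str(platemap_path or ""),
                                   "wells": str(wells_path or "")})
    log.info("run start: mode=%s seed=%d out=%s", mode, run_seed, out)

    def _write(name: str, writer) -> Path:
        path = out / name
        writer(path)
        manifest.outputs.append(name)
        return path

    base, per_construct = _construct_configs(config, run_seed)
    if mode in ("from_simulation", "from_images"):
        try:
            plate = (read_platemap(platemap_path, config.plate.plate_format)
                     if platemap_path else build_plate_for_config(config, run_seed))
        except Exception as exc:
            raise PipelineError("platemap", str(exc)) from exc
        _write("platemap.csv", plate.to_csv)
        log.info("plate: %d wells, %d constructs", len(plate), len(plate.constructs))
        try:
            truth = simulate_plate(base, plate, construct_configs=per_construct)
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc
        _write("truth.json", truth.save_truth)
        if mode == "from_simulation":
            wells = truth.wells
        else:
            wells = render_and_quantify_plate(truth, config, run_seed)
            log.info("rendered and re-quantified %d wells", len(wells))
    else:
        if wells_path is None:
            raise PipelineError("read_counts", "from_counts mode requires wells_path")
        plate = (read_platemap(platemap_path, config.plate.plate_format)
                 if platemap_path else None)
        wells = read_wells_csv(wells_path, plate)
        log.info("loaded %d well series", len(wells))

    _write("wells.csv", lambda p: wells_to_frame(wells).to_csv(p, index=False))

    try:
        profiles = build_profiles(wells, grid_step=config.analysis.grid_step,
                                  lag=config.analysis.lag)
    except Exception as exc:
        raise PipelineError("kinetics", str(exc)) from exc
    _write("profiles.csv", lambda p: profiles_to_frame(profiles).to_csv(p, index=False))
    for prof in profiles:
        for f in prof.flags:
            manifest.flags.append(str(f))
            manifest.flag_counts[f.code] = manifest.flag_counts.get(f.code, 0) + 1
    if manifest.flags:
        log.info("kinetics raised %d flags (%s)", len(manifest.flags),
                 ", ".join(f"{k}={v}" for k, v in sorted(manifest.flag_counts.items())))

    n_doses = min(int(np.sum(p.concentrations > 0)) for p in profiles)
    if n_doses < config.analysis.min_doses_for_fit:
        notice = (f"dose-response skipped: too few doses ({n_doses} positive "
                  f"concentrations < {config.analysis.min_doses_for_fit} required)")
        log.warning(notice)
        _write("summary.txt", lambda p: p.write_text(
            notice + "\n" + "\n".join(manifest.flags) + "\n"))
    else:
        fits = []
        fits_dir = out / "fits"
        fits_dir.mkdir(exist_ok=True)
        for prof in profiles:
            try:
                group_fits = fit_profile(prof, config.analysis)
            except Exception as exc:
                raise PipelineError("dose_response",
                                    f"{prof.construct} @ E:T {prof.et_ratio:g}: {exc}") from exc
            fits.extend(group_fits)
            fname = f"fits/{prof.construct}_ET{prof.et_ratio:g}.json".replace(" ", "_")
            _write(fname, lambda p, gf=group_fits: p.write_text(
                json.dumps([f.to_dict() for f in gf], indent=2)))
        table = summarize(fits)
        _write("summary.csv", lambda p: table.to_csv(p, index=False))
        from .doseresponse import plot_dose_response

        _write("dose_response.png", lambda p: plot_dose_response(
            profiles, fits, p, config.analysis))
        text = summary_text(table)
        if manifest.flags:
            text += "\n\nData-quality flags:\n" + "\n".join(manifest.flags)
        _write("summary.txt", lambda p: p.write_text(text + "\n"))
        log.info("summary: %d fits (%d converged)", len(table),
                 int(table["converged"].sum()))

    manifest.save(out / "manifest.json")
    manifest.outputs.append("manifest.json")
    log.info("run complete: %s", out)
    return out
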