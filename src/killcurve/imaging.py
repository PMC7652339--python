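"""Synthetic frame rendering and three-channel quantification.

The assay consumes three per-timepoint measurements: live effector count
(green-positive, red-negative objects sized 5-15 μm), red pixel area
(dead/dying cells) and phase-contrast occupied pixel area (target
confluency). Vendor segmentation software is proprietary; this module is a
transparent analogue — per-channel thresholding (Otsu by default), connected
components, and a size/shape/red-exclusion gate — validated against the
bundled renderer's ground-truth label maps.

Conventions: the operative "size" is the equivalent diameter
``2*sqrt(area/pi)`` converted to μm; "shape" is circularity
``4*pi*area/perimeter^2``. Effectors are drawn in green only and targets
(live or dead) in phase, matching the simulator's emission model where phase
area tracks targets; dead cells additionally mark the red channel.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage import draw as skdraw
from skimage import measure
from skimage.filters import threshold_otsu

from .config import RenderParams, SegmentationParams
from .kinetics import WellTimeSeries


class ImagingError(ValueError):
    pass


class PackingError(ImagingError):
    """Requested non-overlapping objects cannot be placed in the field."""


@dataclass
class Frame:
    """Co-registered phase/green/red rasters for one well at one time."""

    phase: np.ndarray
    green: np.ndarray
    red: np.ndarray
    microns_per_pixel: float
    time_h: float
    well_id: str

    def __post_init__(self):
        shapes = {self.phase.shape, self.green.shape, self.red.shape}
        if len(shapes) != 1 or self.phase.ndim != 2:
            raise ImagingError("channels must be co-registered 2-D rasters of one shape")
        if self.microns_per_pixel <= 0:
            raise ImagingError("microns_per_pixel must be > 0")
        for name, ch in (("phase", self.phase), ("green", self.green), ("red", self.red)):
            if not np.all(np.isfinite(ch)) or np.any(ch < 0):
                raise ImagingError(f"{name} intensities must be finite and >= 0")


#: object classes the renderer knows about
KINDS = ("effector", "dead_effector", "target", "dead_target")


@dataclass
class RenderedFrame:
    """A rendered frame with its ground truth."""

    frame: Frame
    label_map: np.ndarray          # int32; 0 = background
    objects: pd.DataFrame          # columns: label, kind, row, col, radius_px, area_px


def _place_objects(rng: np.random.Generator, shape: tuple[int, int],
                   radii: list[float], allow_overlap: bool,
                   max_tries_per_object: int) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping disk centers, spatial-hash accelerated."""
    h, w = shape
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    cell = max(2.0 * max(radii, default=1.0) + 1.0, 4.0)
    buckets: dict[tuple[int, int], list[int]] = {}

    def collides(cy: float, cx: float, r: float) -> bool:
        by, bx = int(cy // cell), int(cx // cell)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                for j in buckets.get((by + dy, bx + dx), ()):
                    y0, x0 = centers[j]
                    if (cy - y0) ** 2 + (cx - x0) ** 2 <= (r + placed_r[j] + 2.0) ** 2:
                        return True
        return False

    for r in radii:
        if r + 1 >= min(h, w) / 2:
            raise PackingError(f"object radius {r:.1f} px too large for field {shape}")
        for _ in range(max_tries_per_object):
            cy = rng.uniform(r + 1, h - r - 2)
            cx = rng.uniform(r + 1, w - r - 2)
            if allow_overlap or not collides(cy, cx, r):
                buckets.setdefault((int(cy // cell), int(cx // cell)),
                                   []).append(len(centers))
                centers.append((cy, cx))
                placed_r.append(r)
                break
        else:
            raise PackingError(
                f"could not place {len(radii)} non-overlapping objects in field {shape} "
                f"(stuck after {len(centers)})")
    return centers


def render_frame(n_effectors: int, n_targets_live: int, n_targets_dead: int,
                 params: RenderParams = RenderParams(), seed=0, *,
                 n_dead_effectors: int = 0, time_h: float = 2.0,
                 well_id: str = "W01") -> RenderedFrame:
    """Draw a synthetic three-channel frame with known object ground truth.

    Effectors are green disks with diameters sampled inside the renderer's
    effector range; live/dead targets are larger phase-occupying regions, the
    dead ones red-positive; dead effectors are green+red. Fixed seeds give
    identical rasters. Raises PackingError when non-overlapping placement is
    impossible.
    """
    counts = (n_effectors, n_dead_effectors, n_targets_live, n_targets_dead)
    if any(n < 0 for n in counts):
        raise ImagingError("object counts must be non-negative")
    rng = np.random.default_rng(seed)
    mpp = params.microns_per_pixel

    kinds: list[str] = (["effector"] * n_effectors
                        + ["dead_effector"] * n_dead_effectors
                        + ["target"] * n_targets_live
                        + ["dead_target"] * n_targets_dead)
    diam_range = {"effector": params.effector_diameter_um,
                  "dead_effector": params.effector_diameter_um,
                  "target": params.target_diameter_um,
                  "dead_target": params.dead_diameter_um}
    radii = [rng.uniform(*diam_range[k]) / 2.0 / mpp for k in kinds]
    # place big objects first: improves packing success, order restored after
    order = np.argsort(radii)[::-1]
    centers_sorted = _place_objects(rng, params.shape,
                                    [radii[i] for i in order],
                                    params.allow_overlap, params.max_place_tries)
    centers: list[tuple[float, float]] = [None] * len(kinds)  # type: ignore[list-item]
    for pos, i in enumerate(order):
        centers[i] = centers_sorted[pos]

    phase = np.zeros(params.shape, dtype=np.float64)
    green = np.zeros(params.shape, dtype=np.float64)
    red = np.zeros(params.shape, dtype=np.float64)
    label_map = np.zeros(params.shape, dtype=np.int32)
    records = []
    for idx, (kind, (cy, cx), r) in enumerate(zip(kinds, centers, radii), start=1):
        rr, cc = skdraw.disk((cy, cx), r, shape=params.shape)
        label_map[rr, cc] = idx
        if kind in ("effector", "dead_effector"):
            green[rr, cc] = params.green_intensity * params.effector_intensity_scale
        if kind in ("target", "dead_target"):
            phase[rr, cc] = params.phase_intensity
        if kind in ("dead_effector", "dead_target"):
            red[rr, cc] = params.red_intensity
        records.append({"label": idx, "kind": kind, "row": cy, "col": cx,
                        "radius_px": r, "area_px": len(rr)})

    for ch in (phase, green, red):
        ch += params.background
        if params.noise_sigma > 0:
            ch += rng.normal(0.0, params.noise_sigma, size=ch.shape)
        np.clip(ch, 0.0, None, out=ch)

    frame = Frame(phase=phase, green=green, red=red, microns_per_pixel=mpp,
                  time_h=time_h, well_id=well_id)
    objects = pd.DataFrame(records, columns=["label", "kind", "row", "col",
                                             "radius_px", "area_px"])
    return RenderedFrame(frame=frame, label_map=label_map, objects=objects)


def _auto_threshold(channel: np.ndarray, name: str) -> Optional[float]:
    """Otsu threshold with an empty-channel guard.

    Returns None (and warns) when the channel carries no plausible signal —
    its maximum is indistinguishable from background fluctuation.
    """
    mx = float(channel.max())
    med = float(np.median(channel))
    if mx <= 0 or mx < 3.0 * (med + 1.0):
        warnings.warn(f"{name} channel appears empty; no objects thresholded",
                      stacklevel=3)
        return None
    thr = float(threshold_otsu(channel))
    if float(np.mean(channel >= thr)) > 0.95:
        warnings.warn(f"{name} channel appears saturated above the threshold",
                      stacklevel=3)
    return thr


def count_effectors(frame: Frame, params: SegmentationParams = SegmentationParams()) -> int:
    """Count live effectors: green-positive connected components that pass the
    size gate (equivalent diameter within the configured μm range), the shape
    gate (circularity >= minimum) and the red-exclusion gate (mean red
    intensity below the red threshold)."""
    thr_g = params.green_threshold
    if thr_g is None:
        thr_g = _auto_threshold(frame.green, "green")
        if thr_g is None:
            return 0
    thr_r = params.red_threshold
    if thr_r is None:
        thr_r = _auto_threshold_quiet(frame.red)

    mask = frame.green >= thr_g
    lab = measure.label(mask, connectivity=1)
    lo, hi = params.effector_diameter_range
    n = 0
    for prop in measure.regionprops(lab, intensity_image=frame.red):
        diam_um = prop.equivalent_diameter_area * frame.microns_per_pixel
        if not (lo <= diam_um <= hi):
            continue
        perim = prop.perimeter
        circ = 4.0 * np.pi * prop.area / perim**2 if perim > 0 else 1.0
        if circ < params.min_circularity:
            continue
        if thr_r is not None and prop.intensity_mean >= thr_r:
            continue
        n += 1
    return n


def _auto_threshold_quiet(channel: np.ndarray) -> Optional[float]:
    """Otsu with the empty guard but no warning (absence of red is normal)."""
    mx = float(channel.max())
    med = float(np.median(channel))
    if mx <= 0 or mx < 3.0 * (med + 1.0):
        return None
    return float(threshold_otsu(channel))


def red_area(frame: Frame, params: SegmentationParams = SegmentationParams()) -> int:
    """Red pixel area: count of pixels at or above the red threshold."""
    thr = params.red_threshold
    if thr is None:
        thr = _auto_threshold_quiet(frame.red)
        if thr is None:
            return 0
    return int(np.count_nonzero(frame.red >= thr))


def phase_area(frame: Frame, params: SegmentationParams = SegmentationParams()) -> int:
    """Cell-occupied phase-contrast pixel area (threshold against background)."""
    thr = params.phase_threshold
    if thr is None:
        thr = _auto_threshold_quiet(frame.phase)
        if thr is None:
            return 0
    return int(np.count_nonzero(frame.phase >= thr))


def quantify_stack(frames: Sequence[Frame], params: SegmentationParams = SegmentationParams(),
                   *, construct: str = "unknown", et_ratio: float = 1.0,
                   concentration: float = 0.0) -> WellTimeSeries:
    """Quantify an ordered frame stack into a well time series.

    Frames must share one well id and have strictly increasing times starting
    at the 2 h settling scan.
    """
    if not frames:
        raise ImagingError("empty frame stack")
    wids = {f.well_id for f in frames}
    if len(wids) != 1:
        raise ImagingError(f"frames mix well ids: {sorted(wids)}")
    t = np.array([f.time_h for f in frames], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ImagingError("frame times must be strictly increasing (no duplicates)")
    return WellTimeSeries(
        well_id=frames[0].well_id, construct=construct, et_ratio=et_ratio,
        concentration=concentration, t=t,
        e_live=np.array([count_effectors(f, params) for f in frames], dtype=float),
        red_px=np.array([red_area(f, params) for f in frames], dtype=float),
        phase_px=np.array([phase_area(f, params) for f in frames], dtype=float),
    )


# ---------------------------------------------------------------------------
# frame I/O: multi-page TIFF, filename convention  <well>_t<time>h.tif
# ---------------------------------------------------------------------------

_FNAME_RE = re.compile(r"^(?P<well>[A-Za-z0-9\-]+)_t(?P<time>[0-9]+(?:\.[0-9]+)?)h\.tiff?$")


def frame_filename(well_id: str, time_h: float) -> str:
    return f"{well_id}_t{time_h:07.1f}h.tif"


def write_frame(path: str | Path, frame: Frame) -> Path:
    """Write a frame as a 3-page float32 TIFF (pages: phase, green, red)."""
    path = Path(path)
    meta = {"microns_per_pixel": frame.microns_per_pixel,
            "time_h": frame.time_h, "well_id": frame.well_id,
            "channels": ["phase", "green", "red"]}
    stack = np.stack([frame.phase, frame.green, frame.red]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack",
                     description=json.dumps(meta))
    return path


def read_frame(path: str | Path) -> Frame:
    """Read a frame written by :func:`write_frame`; falls back to the filename
    convention when the TIFF description is absent."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if not meta:
        m = _FNAME_RE.match(path.name)
        if not m:
            raise ImagingError(f"cannot infer well/time for {path.name}; expected "
                               "'<well>_t<time>h.tif' or embedded metadata")
        meta = {"well_id": m.group("well"), "time_h": float(m.group("time")),
                "microns_per_pixel": 1.0}
    if stack.ndim != 3 or stack.shape[0] != 3:
        raise ImagingError(f"{path.name}: expected a 3-page (phase, green, red) TIFF")
    return Frame(phase=stack[0].astype(float), green=stack[1].astype(float),
                 red=stack[2].astype(float),
                 microns_per_pixel=float(meta.get("microns_per_pixel", 1.0)),
                 time_h=float(meta["time_h"]), well_id=str(meta["well_id"]))


def write_label_map(path: str | Path, label_map: np.ndarray) -> Path:
    path = Path(path)
    tifffile.imwrite(path, label_map.astype(np.int32))
    return path
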