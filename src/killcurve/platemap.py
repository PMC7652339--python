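"""Plate-map layout: parsing, validation and programmatic construction.

A plate map is a CSV with one row per well and columns
``well_id, construct, et_ratio, concentration_um, replicate``. Well ids are
row-letter + zero-padded column (``A01`` .. ``P24`` on a 384-well plate).
E:T ratios may be written ``3:1`` style or as decimals. Concentrations are
given in μM in files (the field's reporting unit) and held in molar in
memory. Every (construct, E:T) group must include a 0-dose control well.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

PLATE_DIMS = {96: (8, 12), 384: (16, 24)}
_WELL_RE = re.compile(r"^([A-Pa-p])(\d{1,2})$")


class PlateMapError(ValueError):
    """Aggregated schema violations, each tagged with its file line number."""


def parse_et_ratio(value) -> float:
    """'3:1' -> 3.0, '1:3' -> 1/3, '0.5' -> 0.5."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        ratio = float(value)
    else:
        text = str(value).strip()
        if ":" in text:
            num, den = text.split(":", 1)
            ratio = float(num) / float(den)
        else:
            ratio = float(text)
    if not np.isfinite(ratio) or ratio <= 0:
        raise ValueError(f"E:T ratio must be > 0, got {value!r}")
    return ratio


@dataclass
class PlateMap:
    """Validated plate layout.

    ``frame`` columns: well_id, construct, et_ratio (float), concentration_m
    (molar), replicate (int). ``provenance`` records where the map came from.
    """

    frame: pd.DataFrame
    plate_format: int = 384
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def constructs(self) -> list[str]:
        return sorted(self.frame["construct"].unique())

    @property
    def et_ratios(self) -> list[float]:
        return sorted(self.frame["et_ratio"].unique(), reverse=True)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.frame.copy()
        out["concentration_um"] = out.pop("concentration_m") * 1e6
        out.to_csv(path, index=False,
                   columns=["well_id", "construct", "et_ratio", "concentration_um",
                            "replicate"])
        return path


def _well_sequence(plate_format: int):
    rows, cols = PLATE_DIMS[plate_format]
    for r in range(rows):
        for c in range(cols):
            yield f"{chr(ord('A') + r)}{c + 1:02d}"


def _validate_well_id(well_id: str, plate_format: int) -> str | None:
    m = _WELL_RE.match(str(well_id).strip())
    if not m:
        return f"malformed well id {well_id!r}"
    rows, cols = PLATE_DIMS[plate_format]
    r = ord(m.group(1).upper()) - ord("A")
    c = int(m.group(2))
    if r >= rows or not (1 <= c <= cols):
        return f"well id {well_id!r} outside the {plate_format}-well format"
    return None


def read_platemap(path: str | Path, plate_format: int = 384) -> PlateMap:
    """Parse and validate a plate-map CSV; schema violations are fatal and
    reported together, each with its line number."""
    path = Path(path)
    if not path.exists():
        raise PlateMapError(f"plate map not found: {path}")
    raw = pd.read_csv(path, dtype=str)
    return _validate_platemap(raw, plate_format, provenance=str(path))


def read_platemap_text(text: str, plate_format: int = 384) -> PlateMap:
    raw = pd.read_csv(io.StringIO(text), dtype=str)
    return _validate_platemap(raw, plate_format, provenance="<inline>")


def _validate_platemap(raw: pd.DataFrame, plate_format: int, provenance: str) -> PlateMap:
    errors: list[str] = []
    required = ["well_id", "construct", "et_ratio", "concentration_um"]
    missing_cols = [c for c in required if c not in raw.columns]
    if missing_cols:
        raise PlateMapError(f"missing required columns: {missing_cols}")
    if "replicate" not in raw.columns:
        raw = raw.assign(replicate="1")

    records = []
    line_of: dict[str, list[int]] = {}
    for idx, row in raw.iterrows():
        line = int(idx) + 2  # header is line 1
        wid = str(row["well_id"]).strip().upper()
        err = _validate_well_id(wid, plate_format)
        if err:
            errors.append(f"line {line}: {err}")
            continue
        m = _WELL_RE.match(wid)
        wid = f"{m.group(1)}{int(m.group(2)):02d}"
        line_of.setdefault(wid, []).append(line)
        try:
            ratio = parse_et_ratio(row["et_ratio"])
        except (ValueError, ZeroDivisionError):
            errors.append(f"line {line}: malformed E:T ratio {row['et_ratio']!r}")
            continue
        try:
            conc_um = float(row["concentration_um"])
        except (TypeError, ValueError):
            errors.append(f"line {line}: malformed concentration "
                          f"{row['concentration_um']!r}")
            continue
        if not np.isfinite(conc_um) or conc_um < 0:
            errors.append(f"line {line}: concentration must be >= 0, got {conc_um!r}")
            continue
        try:
            rep = int(float(row["replicate"]))
        except (TypeError, ValueError):
            errors.append(f"line {line}: malformed replicate {row['replicate']!r}")
            continue
        records.append({"well_id": wid, "construct": str(row["construct"]).strip(),
                        "et_ratio": ratio, "concentration_m": conc_um * 1e-6,
                        "replicate": rep})

    for wid, lines in line_of.items():
        if len(lines) > 1:
            errors.append(f"duplicate well id {wid!r} at lines "
                          + " and ".join(map(str, lines)))

    frame = pd.DataFrame(records,
                         columns=["well_id", "construct", "et_ratio",
                                  "concentration_m", "replicate"])
    if not errors:
        for (construct, ratio), grp in frame.groupby(["construct", "et_ratio"]):
            if not (grp["concentration_m"] == 0).any():
                errors.append(f"group {construct!r} @ E:T {ratio:g} lacks the "
                              "mandatory 0 μM control well")
    if errors:
        raise PlateMapError("invalid plate map:\n  " + "\n  ".join(errors))
    return PlateMap(frame=frame, plate_format=plate_format, provenance=provenance)


def build_platemap(constructs: Sequence[str], et_ratios: Sequence[float],
                   concentrations_m: Sequence[float], replicates: int = 2,
                   plate_format: int = 384, provenance: str = "generated") -> PlateMap:
    """Lay out constructs x E:T x doses x replicates row-major onto a plate.

    ``concentrations_m`` are molar and must include the 0 control. Raises if
    the design exceeds plate capacity.
    """
    if 0.0 not in list(concentrations_m):
        raise PlateMapError("concentrations must include the 0 control")
    n_needed = len(constructs) * len(et_ratios) * len(concentrations_m) * replicates
    rows, cols = PLATE_DIMS[plate_format]
    if n_needed > rows * cols:
        raise PlateMapError(f"design needs {n_needed} wells; a {plate_format}-well "
                            "plate cannot hold it")
    wells = _well_sequence(plate_format)
    records = []
    for construct in constructs:
        for ratio in et_ratios:
            for conc in concentrations_m:
                for rep in range(1, replicates + 1):
                    records.append({"well_id": next(wells), "construct": construct,
                                    "et_ratio": float(ratio),
                                    "concentration_m": float(conc), "replicate": rep})
    frame = pd.DataFrame(records)
    return PlateMap(frame=frame, plate_format=plate_format, provenance=provenance)
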