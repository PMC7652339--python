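"""Four-parameter logistic dose-response fitting and the EC50/Emax summary.

Each kinetic readout is reduced to one response per positive concentration
using the assay's peak-time conventions (fold proliferation at ~72 h,
per-T-cell specific killing at ~48 h, rates at their per-dose maximum inside
the 30-72 h window), then fitted with

    r(c) = bottom + (top - bottom) / (1 + (ec50 / c)^hill_slope)

by bounded least squares in log10-concentration space with multi-start
initialisation. Emax is the fitted top plateau. Zero-dose wells are excluded
from fits (log-dose undefined); they serve only the control normalisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import AnalysisParams
from .kinetics import KineticProfile

READOUTS = ("proliferation", "specific_killing", "proliferation_rate", "kill_rate")

#: profile attribute and response units per readout
_READOUT_FIELDS = {
    "proliferation": ("p_fold", "fold increase"),
    "specific_killing": ("s_per_tcell", "per T cell"),
    "proliferation_rate": ("p_prime_pct_day", "%/day"),
    "kill_rate": ("k_prime", "per T cell per hour"),
}


class DoseResponseError(ValueError):
    pass


@dataclass
class ResponseAtPeak:
    """One response value per positive concentration, at the peak-time rule."""

    readout: str
    concentrations: np.ndarray   # molar, > 0
    responses: np.ndarray
    peak_time_h: Optional[float]          # for point-in-time readouts
    selection_rule: str

    def __post_init__(self):
        if len(self.concentrations) != len(self.responses):
            raise DoseResponseError("one response per concentration required")


def extract_peak_response(profile: KineticProfile, readout: str,
                          params: AnalysisParams = AnalysisParams()) -> ResponseAtPeak:
    """Reduce a kinetic profile to the per-dose response the 4PL is fitted to.

    proliferation -> P at the grid time nearest 72 h; specific_killing -> S at
    the grid time nearest 48 h; the two rates -> each dose's maximum over grid
    times inside the 30-72 h window.
    """
    if readout not in READOUTS:
        raise DoseResponseError(f"unknown readout {readout!r}; expected one of {READOUTS}")
    attr, _units = _READOUT_FIELDS[readout]
    values = getattr(profile, attr)
    t = profile.t_grid
    pos = profile.concentrations > 0
    if readout in ("proliferation", "specific_killing"):
        peak = params.prolif_peak_time if readout == "proliferation" else params.kill_peak_time
        if t[-1] + 1e-9 < peak and peak - t[-1] > np.median(np.diff(t)) / 2:
            raise DoseResponseError(
                f"{readout}: grid ends at {t[-1]:g} h, cannot evaluate near {peak:g} h")
        j = int(np.argmin(np.abs(t - peak)))
        resp = values[pos, j]
        return ResponseAtPeak(readout, profile.concentrations[pos], resp, float(t[j]),
                              f"value at grid time nearest {peak:g} h (used {t[j]:g} h)")
    lo, hi = params.rate_window
    in_win = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    if not in_win.any():
        raise DoseResponseError(
            f"{readout}: grid does not cover the {lo:g}-{hi:g} h window")
    with np.errstate(invalid="ignore"):
        resp = np.nanmax(values[np.ix_(pos, in_win)], axis=1)
    return ResponseAtPeak(readout, profile.concentrations[pos], resp, None,
                          f"per-dose maximum over grid times in [{lo:g}, {hi:g}] h")


@dataclass
class DoseResponseFit:
    """4PL parameters and diagnostics for one readout x construct x E:T."""

    readout: str
    construct: str
    et_ratio: float
    bottom: float
    top: float
    ec50: float           # molar
    hill_slope: float
    emax: float           # = top (fitted plateau)
    rss: float
    converged: bool
    n_points: int
    flags: list[str] = field(default_factory=list)

    def predict(self, c) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        return _model4pl(np.log10(c), self.bottom, self.top,
                         math.log10(self.ec50), self.hill_slope)

    def to_dict(self) -> dict:
        return {"readout": self.readout, "construct": self.construct,
                "et_ratio": self.et_ratio, "bottom": self.bottom, "top": self.top,
                "ec50_m": self.ec50, "ec50_um": self.ec50 * 1e6,
                "hill_slope": self.hill_slope, "emax": self.emax, "rss": self.rss,
                "converged": self.converged, "n_points": self.n_points,
                "flags": list(self.flags)}


def _model4pl(logc: np.ndarray, bottom: float, top: float,
              log_ec50: float, slope: float) -> np.ndarray:
    # (ec50/c)^h = 10^(h*(log_ec50 - logc)); logistic form avoids overflow
    z = slope * np.log(10.0) * (logc - log_ec50)
    return bottom + (top - bottom) / (1.0 + np.exp(-np.clip(z, -700, 700)))


def fit_4pl(concentrations: Sequence[float], responses: Sequence[float],
            readout: str = "", construct: str = "", et_ratio: float = float("nan"),
            n_starts: int = 5) -> DoseResponseFit:
    """Bounded least-squares 4PL fit in log10-dose space, multi-start on EC50.

    Requires >= 5 distinct positive concentrations with finite responses.
    Hill slope is bounded to [0.1, 10] and EC50 to [min dose/10, max dose*10].
    A response with no dose dependence (4PL not significantly better than a
    constant, or a collapsed plateau span) is flagged ``no_dose_dependence``.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(responses, dtype=float)
    if c.shape != r.shape:
        raise DoseResponseError("concentrations and responses must match in length")
    keep = np.isfinite(r)
    c, r = c[keep], r[keep]
    if np.any(c <= 0):
        raise DoseResponseError("4PL fit requires positive concentrations (c = 0 excluded)")
    if len(np.unique(c)) < 5:
        raise DoseResponseError("4PL fit requires >= 5 distinct positive concentrations")
    order = np.argsort(c)
    c, r = c[order], r[order]
    logc = np.log10(c)

    flags: list[str] = []
    rmin, rmax = float(r.min()), float(r.max())
    span = rmax - rmin
    scale = max(abs(rmin), abs(rmax), 1e-300)
    if span <= 1e-12 * scale:
        # all responses identical: constant curve, EC50 unidentifiable
        return DoseResponseFit(readout, construct, et_ratio, bottom=rmin, top=rmax,
                               ec50=float(np.sqrt(c[0] * c[-1])), hill_slope=1.0,
                               emax=rmax, rss=0.0, converged=True, n_points=len(c),
                               flags=["no_dose_dependence", "flat_response",
                                      "ec50_unreliable"])

    pad = 0.5 * span
    lb = [rmin - 10 * span, rmin - 10 * span, logc[0] - 1.0, 0.1]
    ub = [rmax + 10 * span, rmax + 10 * span, logc[-1] + 1.0, 10.0]
    starts = np.linspace(logc[0], logc[-1], n_starts)
    best = None
    for s0 in starts:
        for b0, t0 in ((rmin, rmax), (rmax, rmin)):
            p0 = [float(np.clip(b0, lb[0] + 1e-12, ub[0] - 1e-12)),
                  float(np.clip(t0 + (pad if t0 >= b0 else -pad), lb[1] + 1e-12, ub[1] - 1e-12)),
                  float(s0), 1.0]
            try:
                popt, _ = optimize.curve_fit(_model4pl, logc, r, p0=p0,
                                             bounds=(lb, ub), method="trf",
                                             maxfev=20000)
            except (RuntimeError, optimize.OptimizeWarning, ValueError):
                continue
            rss = float(np.sum((_model4pl(logc, *popt) - r) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
    if best is None:
        return DoseResponseFit(readout, construct, et_ratio, bottom=float("nan"),
                               top=float("nan"), ec50=float("nan"),
                               hill_slope=float("nan"), emax=float("nan"),
                               rss=float("inf"), converged=False, n_points=len(c),
                               flags=["non_convergent"])
    (bottom, top, log_ec50, slope), rss = best

    # dose-dependence check: 4PL vs constant-mean model, partial F-test
    rss_const = float(np.sum((r - r.mean()) ** 2))
    n, p_full, p_null = len(r), 4, 1
    if n > p_full and rss > 0:
        f_stat = ((rss_const - rss) / (p_full - p_null)) / (rss / (n - p_full))
        p_val = float(stats.f.sf(max(f_stat, 0.0), p_full - p_null, n - p_full))
    else:
        p_val = 0.0 if rss_const > rss else 1.0
    resid_sd = math.sqrt(rss / max(n - p_full, 1))
    if p_val > 1e-3 or abs(top - bottom) < 2.0 * resid_sd:
        flags += ["no_dose_dependence", "ec50_unreliable"]

    return DoseResponseFit(readout, construct, et_ratio, bottom=float(bottom),
                           top=float(top), ec50=float(10 ** log_ec50),
                           hill_slope=float(slope), emax=float(top), rss=rss,
                           converged=True, n_points=len(c), flags=flags)


def fit_profile(profile: KineticProfile, params: AnalysisParams = AnalysisParams(),
                readouts: Sequence[str] = READOUTS) -> list[DoseResponseFit]:
    """Peak-extract and 4PL-fit every requested readout of one profile."""
    fits = []
    for readout in readouts:
        peak = extract_peak_response(profile, readout, params)
        fits.append(fit_4pl(peak.concentrations, peak.responses, readout=readout,
                            construct=profile.construct, et_ratio=profile.et_ratio))
    return fits


def format_et_ratio(et_ratio: float) -> str:
    """3.0 -> '3:1', 0.333... -> '1:3'."""
    frac = Fraction(et_ratio).limit_denominator(100)
    return f"{frac.numerator}:{frac.denominator}"


def summarize(fits: Sequence[DoseResponseFit]) -> pd.DataFrame:
    """Long-format EC50/Emax summary table; non-converged fits keep their row
    with an empty EC50."""
    rows = []
    for f in sorted(fits, key=lambda f: (f.construct, -f.et_ratio,
                                         READOUTS.index(f.readout))):
        ok = f.converged
        rows.append({
            "construct": f.construct,
            "et_ratio": format_et_ratio(f.et_ratio),
            "readout": f.readout,
            "ec50_um": f.ec50 * 1e6 if ok else np.nan,
            "emax": f.emax if ok else np.nan,
            "emax_units": _READOUT_FIELDS[f.readout][1],
            "hill_slope": f.hill_slope if ok else np.nan,
            "rss": f.rss,
            "converged": ok,
            "n_points": f.n_points,
            "flags": ";".join(f.flags),
        })
    return pd.DataFrame(rows)


def summary_text(table: pd.DataFrame) -> str:
    """Human-readable aligned-text rendering of the summary table."""
    show = table.copy()
    show["ec50_um"] = show["ec50_um"].map(lambda v: f"{v:.4g}" if np.isfinite(v) else "-")
    show["emax"] = show["emax"].map(lambda v: f"{v:.4g}" if np.isfinite(v) else "-")
    show["hill_slope"] = show["hill_slope"].map(
        lambda v: f"{v:.3g}" if np.isfinite(v) else "-")
    cols = ["construct", "et_ratio", "readout", "ec50_um", "emax", "emax_units",
            "hill_slope", "converged", "flags"]
    return show[cols].to_string(index=False)


def plot_dose_response(profiles, fits: Sequence[DoseResponseFit], path,
                       params: AnalysisParams = AnalysisParams()) -> None:
    """Static summary figure: one panel per readout, peak responses as points
    and converged 4PL curves as lines, per (construct, E:T) group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 8), sharex=True)
    by_group = {(f.construct, f.et_ratio, f.readout): f for f in fits}
    for ax, readout in zip(axes.ravel(), READOUTS):
        for prof in profiles:
            peak = extract_peak_response(prof, readout, params)
            c_um = peak.concentrations * 1e6
            label = f"{prof.construct} {format_et_ratio(prof.et_ratio)}"
            pts = ax.plot(c_um, peak.responses, "o", ms=3, alpha=0.6, label=label)
            fit = by_group.get((prof.construct, prof.et_ratio, readout))
            if fit is not None and fit.converged and "non_convergent" not in fit.flags:
                grid = np.geomspace(c_um.min(), c_um.max(), 120)
                ax.plot(grid, fit.predict(grid * 1e-6), "-", lw=1,
                        color=pts[0].get_color())
        ax.set_xscale("log")
        ax.set_title(readout)
        ax.set_xlabel("peptide (μM)")
        ax.set_ylabel(_READOUT_FIELDS[readout][1])
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def band_concentrations(ec50: float, concentrations: Sequence[float]) -> dict[float, str]:
    """Assign each positive dose a band relative to a fitted EC50.

    High: c >= 100 x EC50; Mid: EC50 <= c < 100 x EC50; Low: c < EC50.
    Boundary doses go to the higher band. Every positive dose lands in
    exactly one band.
    """
    if not (np.isfinite(ec50) and ec50 > 0):
        raise DoseResponseError("banding requires a converged EC50 > 0")
    out: dict[float, str] = {}
    for c in concentrations:
        if c <= 0 or not np.isfinite(c):
            raise DoseResponseError(f"banding applies to positive doses only, got {c!r}")
        if c >= 100.0 * ec50:
            out[float(c)] = "High"
        elif c >= ec50:
            out[float(c)] = "Mid"
        else:
            out[float(c)] = "Low"
    return out
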