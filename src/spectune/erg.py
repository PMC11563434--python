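"""ERG flash-response analysis: V-log(I) curves, Boltzmann fits, thresholds.

The processing chain mirrors standard corneal-ERG practice for spectral
sensitivity work:

1.  DC correction: a session starts with "no light" flashes; their averaged,
    time-averaged level is subtracted from every trace.
2.  Flash averaging: responses at one (wavelength, intensity) are the mean
    of (nominally four) flashes; a trace whose pre-stimulus RMS exceeds
    5x the median of the set is rejected as an artifact (at most one, and
    at least three traces must remain).
3.  b-wave measurement: by default the voltage difference between the
    a-wave trough (minimum within 60 ms of flash onset) and the later
    b-wave peak (maximum within 20-200 ms of onset); baseline-to-peak is
    available as an alternative convention.
4.  Normalization to relative amplitude: b-wave amplitude divided by the
    maximum within the normalization unit — per (animal, wavelength) by
    default, or per animal globally.
5.  Boltzmann fit per (animal, wavelength): relative amplitude as a
    function of flash = log10 intensity,

        V(flash) = (A1 - A2) / (1 + exp((flash - flash0) / tau)) + A2,

    with the asymptotes fixed at A1 = 0 and A2 = 1, leaving the half-max
    intensity flash0 and the slope tau > 0 as the free parameters.
6.  Threshold: the intensity at 10% of maximum response, which inverts
    analytically to  flash0 - tau * ln 9.
7.  Tuning curve: group mean threshold (± SE) per stimulus wavelength.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "WAVELENGTHS_NM",
    "LN9",
    "ERGTrace",
    "BoltzmannFit",
    "ThresholdEstimate",
    "dc_correct",
    "average_flashes",
    "measure_bwave",
    "normalize_amplitudes",
    "boltzmann_value",
    "fit_boltzmann",
    "threshold_10pct",
    "build_tuning_curve",
    "analyze_amplitude_table",
]

#: the study's stimulus wavelengths (350 nm only for a subset of animals)
WAVELENGTHS_NM = (350, 400, 450, 500, 550, 600, 650)

#: ln 9 — the offset (in units of tau) between the 50% and 10% points
LN9 = math.log(9.0)

#: artifact rejection: pre-stimulus RMS above this multiple of the set median
REJECTION_FACTOR = 5.0

# b-wave measurement windows, ms after flash onset
A_WAVE_WINDOW_MS = (0.0, 60.0)
B_WAVE_WINDOW_MS = (20.0, 200.0)


@dataclass
class ERGTrace:
    """One flash-evoked voltage record with its stimulus bookkeeping."""

    time_ms: np.ndarray
    voltage_uv: np.ndarray
    animal_id: str
    wavelength_nm: int | None  # None for a no-light flash
    log_intensity: float | None
    flash_onset_ms: float
    no_light: bool = False

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.voltage_uv = np.asarray(self.voltage_uv, dtype=float)
        if self.time_ms.shape != self.voltage_uv.shape:
            raise ValueError("time and voltage must have equal length")
        dt = np.diff(self.time_ms)
        if len(dt) and not np.allclose(dt, dt[0]):
            raise ValueError("trace must be uniformly sampled")
        if not (self.time_ms[0] <= self.flash_onset_ms <= self.time_ms[-1]):
            raise ValueError("flash onset outside the recorded window")

    def _pre_stimulus(self) -> np.ndarray:
        return self.voltage_uv[self.time_ms < self.flash_onset_ms]


@dataclass
class BoltzmannFit:
    """Fitted sigmoid for one (animal, wavelength) V-log(I) curve.

    The asymptotes are fixed constants (a1 = 0, a2 = 1); flash0 is the
    log10 intensity producing half the maximum response and tau the slope.
    """

    flash0: float
    tau: float
    rss: float
    n_points: int
    converged: bool
    a1: float = 0.0
    a2: float = 1.0
    note: str = ""


@dataclass
class ThresholdEstimate:
    """The 10%-of-maximum threshold intensity for one fit."""

    animal_id: str
    wavelength_nm: int
    threshold_log_intensity: float
    extrapolated: bool = False


def _check_same_sampling(traces: Sequence[ERGTrace]) -> None:
    ref = traces[0].time_ms
    for t in traces[1:]:
        if t.time_ms.shape != ref.shape or not np.allclose(t.time_ms, ref):
            raise ValueError("traces have mismatched sampling grids")


def dc_correct(traces: Sequence[ERGTrace], no_light_traces: Sequence[ERGTrace]) -> list[ERGTrace]:
    """Subtract the DC level measured from the no-light flashes.

    The correction is the time-averaged mean of the averaged no-light
    response, applied uniformly to every stimulus trace.
    """
    if not no_light_traces:
        raise ValueError("at least one no-light trace is required for DC correction")
    _check_same_sampling(list(no_light_traces) + list(traces))
    avg_no_light = np.mean([t.voltage_uv for t in no_light_traces], axis=0)
    dc = float(np.mean(avg_no_light))
    out = []
    for t in traces:
        out.append(ERGTrace(
            t.time_ms, t.voltage_uv - dc, t.animal_id, t.wavelength_nm,
            t.log_intensity, t.flash_onset_ms, t.no_light,
        ))
    return out


def average_flashes(
    traces: Sequence[ERGTrace],
    rejection_factor: float = REJECTION_FACTOR,
) -> tuple[ERGTrace, int]:
    """Average repeated flashes at one (wavelength, intensity) step.

    A trace whose pre-stimulus RMS (about its own pre-stimulus mean)
    exceeds ``rejection_factor`` times the median RMS of the set is
    excluded as spurious noise.  At most one trace may be rejected and at
    least three must remain; otherwise the step is flagged for manual
    review via ValueError.
    """
    traces = list(traces)
    if len(traces) < 3:
        raise ValueError(f"need >= 3 traces to average, got {len(traces)}")
    _check_same_sampling(traces)
    # RMS about each trace's own pre-stimulus mean, so a pure DC shift
    # does not read as an artifact
    rms = np.array([float(np.std(t._pre_stimulus())) for t in traces])
    med = float(np.median(rms))
    noisy = rms > rejection_factor * med if med > 0 else np.zeros(len(traces), bool)
    if noisy.sum() > 1:
        raise ValueError(
            f"{int(noisy.sum())} traces exceed {rejection_factor}x the median "
            "pre-stimulus RMS; step flagged for manual review"
        )
    keep = [t for t, bad in zip(traces, noisy) if not bad]
    if len(keep) < 3:
        raise ValueError("fewer than 3 traces remain after artifact rejection")
    ref = keep[0]
    mean_v = np.mean([t.voltage_uv for t in keep], axis=0)
    avg = ERGTrace(ref.time_ms, mean_v, ref.animal_id, ref.wavelength_nm,
                   ref.log_intensity, ref.flash_onset_ms, ref.no_light)
    return avg, len(keep)


def measure_bwave(trace: ERGTrace, mode: str = "trough_to_peak") -> float:
    """b-wave amplitude (μV) of a DC-corrected averaged trace.

    ``trough_to_peak`` (default): voltage difference from the a-wave trough
    (minimum within 60 ms of onset) to the later b-wave peak (maximum
    within 20-200 ms of onset).  ``baseline_to_peak``: the b-wave peak
    voltage itself.  If the peak does not occur later than the trough the
    measurement falls back to baseline-to-peak with a warning.
    """
    if mode not in {"trough_to_peak", "baseline_to_peak"}:
        raise ValueError(f"unknown b-wave mode {mode!r}")
    t = trace.time_ms - trace.flash_onset_ms
    v = trace.voltage_uv
    a_win = (t >= A_WAVE_WINDOW_MS[0]) & (t <= A_WAVE_WINDOW_MS[1])
    b_win = (t >= B_WAVE_WINDOW_MS[0]) & (t <= B_WAVE_WINDOW_MS[1])
    if not a_win.any() or not b_win.any():
        raise ValueError("trace too short for the a-/b-wave windows")
    trough_idx = np.flatnonzero(a_win)[np.argmin(v[a_win])]
    peak_idx = np.flatnonzero(b_win)[np.argmax(v[b_win])]
    if mode == "baseline_to_peak":
        return float(v[peak_idx])
    if peak_idx <= trough_idx:
        warnings.warn(
            "b-wave peak not later than a-wave trough; falling back to "
            "baseline-to-peak", RuntimeWarning, stacklevel=2)
        return float(v[peak_idx])
    return float(v[peak_idx] - v[trough_idx])


def normalize_amplitudes(points: pd.DataFrame, mode: str = "per_wavelength") -> pd.DataFrame:
    """Convert b-wave amplitudes to relative amplitudes in [0, 1].

    ``points`` needs columns ``animal_id, wavelength_nm, log_intensity,
    bwave_uv``.  Mode ``per_wavelength`` (default) divides by the maximum
    within each (animal, wavelength); ``per_animal`` divides by the
    animal's global maximum.  The maximum of each normalization unit is
    exactly 1; a unit whose amplitudes are all zero is rejected.
    """
    if mode not in {"per_wavelength", "per_animal"}:
        raise ValueError(f"unknown normalization mode {mode!r}")
    required = {"animal_id", "wavelength_nm", "log_intensity", "bwave_uv"}
    missing = required - set(points.columns)
    if missing:
        raise ValueError(f"amplitude table missing columns: {sorted(missing)}")
    keys = ["animal_id"] if mode == "per_animal" else ["animal_id", "wavelength_nm"]
    out = points.copy()
    maxima = out.groupby(keys)["bwave_uv"].transform("max")
    if (maxima <= 0).any():
        unit = out.loc[maxima <= 0, keys].iloc[0].tolist()
        raise ValueError(f"all-zero amplitudes in normalization unit {unit}")
    out["relative_amplitude"] = out["bwave_uv"] / maxima
    return out


def boltzmann_value(flash, flash0: float, tau: float):
    """Relative b-wave amplitude predicted by the fixed-asymptote sigmoid.

    (A1 - A2)/(1 + exp((flash - flash0)/tau)) + A2 with A1 = 0, A2 = 1;
    equals 0.5 at flash = flash0 and is strictly increasing in flash.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    x = (np.asarray(flash, dtype=float) - flash0) / tau
    # numerically stable logistic
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)),
                   np.exp(np.clip(x, -745, 0)) / (1.0 + np.exp(np.clip(x, -745, 0))))
    return out if out.ndim else float(out)


#: minimum spread of relative amplitudes for an identifiable fit
MIN_DYNAMIC_RANGE = 0.3


def fit_boltzmann(points: pd.DataFrame | None = None, *,
                  flash: Sequence[float] | None = None,
                  relative_amplitude: Sequence[float] | None = None) -> BoltzmannFit:
    """Least-squares Boltzmann fit for one (animal, wavelength).

    Accepts either a DataFrame with ``log_intensity`` and
    ``relative_amplitude`` columns or the two arrays directly.  Requires
    >= 4 points; a dynamic range (max - min relative amplitude) below 0.3
    yields a flagged, unconverged fit that downstream tuning curves drop.
    flash0 is initialised at the intensity of the point nearest 0.5 and
    tau at a quarter of the tested intensity range; tau is constrained
    positive and the solver runs to 1e-10 parameter tolerance.
    """
    if points is not None:
        flash = points["log_intensity"].to_numpy(dtype=float)
        relative_amplitude = points["relative_amplitude"].to_numpy(dtype=float)
    x = np.asarray(flash, dtype=float)
    y = np.asarray(relative_amplitude, dtype=float)
    if len(x) != len(y):
        raise ValueError("flash and amplitude arrays differ in length")
    if len(x) < 4:
        raise ValueError(f"need >= 4 points for a Boltzmann fit, got {len(x)}")

    dynamic_range = float(y.max() - y.min())
    if dynamic_range < MIN_DYNAMIC_RANGE:
        return BoltzmannFit(np.nan, np.nan, np.nan, len(x), converged=False,
                            note=f"dynamic range {dynamic_range:.3f} < {MIN_DYNAMIC_RANGE}")

    f0_init = float(x[np.argmin(np.abs(y - 0.5))])
    tau_init = max(float(x.max() - x.min()) / 4.0, 1e-3)

    def residuals(p):
        return boltzmann_value(x, p[0], p[1]) - y

    sol = least_squares(residuals, [f0_init, tau_init],
                        bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
                        xtol=1e-10, ftol=1e-12, gtol=1e-12)
    rss = float(np.sum(sol.fun ** 2))
    return BoltzmannFit(float(sol.x[0]), float(sol.x[1]), rss, len(x),
                        converged=bool(sol.success),
                        note="" if sol.success else "solver did not converge")


def threshold_10pct(fit: BoltzmannFit, animal_id: str = "", wavelength_nm: int = 0,
                    tested_range: tuple[float, float] | None = None) -> ThresholdEstimate:
    """Intensity eliciting 10% of the maximum response, from the fit.

    The Boltzmann inverts analytically: V = 0.1 at flash0 - tau * ln 9.
    The ``extrapolated`` flag marks thresholds below the lowest tested
    intensity.  Unconverged fits are rejected.
    """
    if not fit.converged:
        raise ValueError(f"cannot take a threshold from an unconverged fit ({fit.note})")
    thr = fit.flash0 - fit.tau * LN9
    extrapolated = tested_range is not None and thr < tested_range[0]
    return ThresholdEstimate(animal_id, wavelength_nm, float(thr), bool(extrapolated))


def build_tuning_curve(thresholds: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Group-level spectral tuning curve: mean threshold (± SE) per wavelength.

    ``thresholds`` needs ``wavelength_nm``, ``threshold_log_intensity`` and
    the grouping column.  SE is NaN when a cell holds one animal; cells
    with no data (e.g. 350 nm measured only in some groups) are simply
    absent from the output.
    """
    if thresholds.empty:
        raise ValueError("no thresholds supplied")
    for col in (group_col, "wavelength_nm", "threshold_log_intensity"):
        if col not in thresholds.columns:
            raise ValueError(f"thresholds table missing column {col!r}")
    grouped = thresholds.groupby([group_col, "wavelength_nm"])["threshold_log_intensity"]
    out = grouped.agg(mean_threshold="mean", sd="std", n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] == 1, "se"] = np.nan
    out = out.drop(columns="sd").rename(columns={group_col: "group"})
    return out.sort_values(["group", "wavelength_nm"], ignore_index=True)


def analyze_amplitude_table(
    amplitudes: pd.DataFrame,
    normalization: str = "per_wavelength",
    group_col: str | None = "group",
) -> dict[str, pd.DataFrame]:
    """Run the amplitude-table half of the pipeline in one call.

    ``amplitudes`` is the pre-extracted table ``animal_id, wavelength_nm,
    log_intensity, bwave_uv`` (plus any grouping columns, carried
    through).  Returns the V-log(I) point table, the per-(animal,
    wavelength) fits table, the thresholds table, and — when ``group_col``
    is present — the tuning curve.
    """
    points = normalize_amplitudes(amplitudes, mode=normalization)
    extra_cols = [c for c in points.columns
                  if c not in {"log_intensity", "bwave_uv", "relative_amplitude"}]
    fits, thresholds = [], []
    for (animal, wl), grp in points.groupby(["animal_id", "wavelength_nm"]):
        fit = fit_boltzmann(grp)
        labels = {c: grp[c].iloc[0] for c in extra_cols}
        fits.append({**labels, "flash0": fit.flash0, "tau": fit.tau,
                     "rss": fit.rss, "n_points": fit.n_points,
                     "converged": fit.converged, "note": fit.note})
        if fit.converged:
            rng = (float(grp["log_intensity"].min()), float(grp["log_intensity"].max()))
            est = threshold_10pct(fit, animal, int(wl), tested_range=rng)
            thresholds.append({**labels,
                               "threshold_log_intensity": est.threshold_log_intensity,
                               "extrapolated": est.extrapolated})
    fits_df = pd.DataFrame(fits)
    thr_df = pd.DataFrame(thresholds)
    result = {"points": points, "fits": fits_df, "thresholds": thr_df}
    if group_col and not thr_df.empty and group_col in thr_df.columns:
        result["tuning"] = build_tuning_curve(thr_df, group_col=group_col)
    return result
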