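"""Spectrometer reflectance curves and their summary metrics.

A reflectance curve is percent reflectance relative to a diffuse white
standard, sampled on a strictly increasing wavelength grid (typically
300-700 nm).  Each curve is summarised by four metrics used throughout the
downstream statistics:

peak_nm
    wavelength of maximum reflectance (ties broken toward the lowest
    wavelength and flagged),
fwhm_nm
    full width at half maximum -- the distance between the half-maximum
    crossings nearest the peak on either side, found by linear
    interpolation and clipped (with a flag) to the grid boundary when a
    side never drops below half max,
auc_pct_nm
    trapezoidal integral of the curve above a 0% baseline (a
    min-of-curve baseline is available as an option),
avg_pct
    arithmetic mean of all reflectance samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumCurve",
    "SpectrumMetrics",
    "read_spectrum",
    "compute_metrics",
    "metrics_table",
    "summarize_group",
]

#: surface regions recognised in curve metadata
REGIONS = ("dorsal", "lateral", "axillary", "inguinal")

#: metric column names, in canonical order
METRIC_COLUMNS = ("peak_nm", "fwhm_nm", "auc_pct_nm", "avg_pct")


@dataclass
class SpectrumCurve:
    """A wavelength-indexed percent-reflectance series plus specimen metadata.

    Wavelengths must be strictly increasing and reflectance non-negative;
    both arrays must have equal length >= 3.
    """

    wavelength_nm: np.ndarray
    reflectance_pct: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.reflectance_pct = np.asarray(self.reflectance_pct, dtype=float)
        if self.wavelength_nm.ndim != 1 or self.reflectance_pct.ndim != 1:
            raise ValueError("wavelength and reflectance must be 1-D")
        if len(self.wavelength_nm) != len(self.reflectance_pct):
            raise ValueError(
                f"length mismatch: {len(self.wavelength_nm)} wavelengths vs "
                f"{len(self.reflectance_pct)} reflectance values"
            )
        if len(self.wavelength_nm) < 3:
            raise ValueError("a spectrum needs at least 3 samples")
        if not np.all(np.diff(self.wavelength_nm) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.reflectance_pct < 0):
            idx = int(np.argmax(self.reflectance_pct < 0))
            raise ValueError(
                f"negative reflectance at sample {idx} "
                f"(wavelength {self.wavelength_nm[idx]:g} nm)"
            )

    def __len__(self) -> int:
        return len(self.wavelength_nm)


@dataclass
class SpectrumMetrics:
    """The four curve summary metrics plus quality flags."""

    peak_nm: float | None
    fwhm_nm: float | None
    auc_pct_nm: float
    avg_pct: float
    peak_tied: bool = False
    peak_undefined: bool = False
    fwhm_clipped_low: bool = False
    fwhm_clipped_high: bool = False

    def as_dict(self) -> dict:
        return {
            "peak_nm": self.peak_nm,
            "fwhm_nm": self.fwhm_nm,
            "auc_pct_nm": self.auc_pct_nm,
            "avg_pct": self.avg_pct,
            "peak_tied": self.peak_tied,
            "peak_undefined": self.peak_undefined,
            "fwhm_clipped_low": self.fwhm_clipped_low,
            "fwhm_clipped_high": self.fwhm_clipped_high,
        }


def read_spectrum(path: str | Path, meta: Mapping | None = None) -> SpectrumCurve:
    """Read a two-column ``wavelength,reflectance`` CSV/TSV into a curve.

    The file has one header line.  Rows are sorted by wavelength and
    duplicate wavelengths are collapsed by their mean.  Non-numeric rows,
    fewer than 3 points, or negative reflectance are rejected with a
    row-level message.  A JSON sidecar ``<path>.meta.json`` is merged into
    the curve metadata when present; an explicit ``meta`` mapping wins.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except Exception as exc:  # parse failure from pandas
        raise ValueError(f"{path}: cannot parse spectrum file: {exc}") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns, found {df.shape[1]}")
    df = df.iloc[:, :2].copy()
    df.columns = ["wavelength_nm", "reflectance_pct"]
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            bad = int(np.argmax(numeric.isna().to_numpy()))
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at data row {bad}"
            )
        df[col] = numeric
    if (df["reflectance_pct"] < 0).any():
        bad = int(np.argmax((df["reflectance_pct"] < 0).to_numpy()))
        raise ValueError(f"{path}: negative reflectance at data row {bad}")
    df = df.groupby("wavelength_nm", as_index=False)["reflectance_pct"].mean()
    df = df.sort_values("wavelength_nm")
    if len(df) < 3:
        raise ValueError(f"{path}: fewer than 3 distinct wavelengths")

    merged: dict = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        merged.update(json.loads(sidecar.read_text()))
    if meta:
        merged.update(meta)
    return SpectrumCurve(
        df["wavelength_nm"].to_numpy(), df["reflectance_pct"].to_numpy(), merged
    )


def _half_crossing(wl: np.ndarray, r: np.ndarray, half: float, peak_idx: int,
                   side: str) -> tuple[float, bool]:
    """Interpolated half-max crossing nearest the peak on one side.

    Returns (wavelength, clipped) where clipped means the curve never
    dropped below half on that side and the grid boundary was used.
    """
    if side == "low":
        indices = range(peak_idx - 1, -1, -1)
        boundary = wl[0]
    else:
        indices = range(peak_idx + 1, len(wl))
        boundary = wl[-1]
    prev = peak_idx
    for i in indices:
        if r[i] < half:
            # linear interpolation between samples prev (>= half) and i (< half)
            w0, w1 = wl[prev], wl[i]
            r0, r1 = r[prev], r[i]
            return w0 + (half - r0) * (w1 - w0) / (r1 - r0), False
        prev = i
    return boundary, True


def compute_metrics(curve: SpectrumCurve, auc_baseline: str = "zero") -> SpectrumMetrics:
    """Compute peak, FWHM, AUC, and average reflectance for one curve.

    ``auc_baseline`` is ``"zero"`` (default: integrate the curve above 0%
    reflectance) or ``"min"`` (subtract the curve minimum first).
    An all-zero curve yields an undefined peak and FWHM with AUC = 0.
    """
    if auc_baseline not in {"zero", "min"}:
        raise ValueError(f"unknown auc_baseline {auc_baseline!r}")
    wl = curve.wavelength_nm
    r = curve.reflectance_pct
    avg = float(np.mean(r))
    base = float(np.min(r)) if auc_baseline == "min" else 0.0
    auc = float(np.trapezoid(r - base, wl))

    rmax = float(np.max(r))
    if rmax == 0.0:
        return SpectrumMetrics(None, None, auc, avg, peak_undefined=True)

    peak_indices = np.flatnonzero(r == rmax)
    peak_idx = int(peak_indices[0])  # tie-break toward the lowest wavelength
    tied = len(peak_indices) > 1
    half = rmax / 2.0
    lo, clip_lo = _half_crossing(wl, r, half, peak_idx, "low")
    hi, clip_hi = _half_crossing(wl, r, half, peak_idx, "high")
    return SpectrumMetrics(
        peak_nm=float(wl[peak_idx]),
        fwhm_nm=float(hi - lo),
        auc_pct_nm=auc,
        avg_pct=avg,
        peak_tied=tied,
        fwhm_clipped_low=clip_lo,
        fwhm_clipped_high=clip_hi,
    )


def metrics_table(curves: Iterable[SpectrumCurve], auc_baseline: str = "zero") -> pd.DataFrame:
    """One metrics row per curve, with metadata columns carried through."""
    rows = []
    for curve in curves:
        row = dict(curve.meta)
        row.pop("truth", None)  # synthetic ground truth is not a metric
        row.update(compute_metrics(curve, auc_baseline=auc_baseline).as_dict())
        rows.append(row)
    if not rows:
        raise ValueError("no curves supplied")
    return pd.DataFrame(rows)


def summarize_group(
    curves: Sequence[SpectrumCurve],
    group_key: str | None = None,
) -> pd.DataFrame:
    """Per-wavelength mean and standard error of curves, optionally by group.

    ``group_key`` names a metadata field; ``None`` treats all curves as one
    group.  Curves on different grids are linearly re-interpolated onto the
    intersection range of the first curve's grid.  SE is reported missing
    (NaN) for cells with a single curve.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("empty group: no curves to summarize")

    lo = max(c.wavelength_nm[0] for c in curves)
    hi = min(c.wavelength_nm[-1] for c in curves)
    if lo >= hi:
        raise ValueError("curves have no common wavelength range")
    ref = curves[0].wavelength_nm
    grid = ref[(ref >= lo) & (ref <= hi)]

    records = []
    for c in curves:
        vals = np.interp(grid, c.wavelength_nm, c.reflectance_pct)
        label = c.meta.get(group_key, None) if group_key else "all"
        records.append((label, vals))

    out = []
    for label in sorted({lab for lab, _ in records}, key=str):
        stack = np.vstack([v for lab, v in records if lab == label])
        n = stack.shape[0]
        mean = stack.mean(axis=0)
        se = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full(len(grid), np.nan)
        out.append(pd.DataFrame({
            "group": label,
            "wavelength_nm": grid,
            "mean_pct": mean,
            "se_pct": se,
            "n": n,
        }))
    return pd.concat(out, ignore_index=True)
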