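"""Seeded synthetic-data generators with recorded ground truth.

Every downstream stage of the package can be exercised without external
data: reflectance spectra are smooth baselines plus 0-2 Gaussian peaks
with additive noise; marking tables carry per-surface area fractions that
sum to at most 1; ERG experiments produce flash-evoked voltage traces
whose noiseless b-wave amplitude follows the Boltzmann intensity-response
law, together with no-light flashes carrying only the DC offset, and
optional artifact traces with inflated pre-stimulus noise.

The ERG waveform template is a negative Gaussian a-deflection (trough
30 ms after flash onset) followed by a positive Gaussian b-deflection
(peak at 80 ms), scaled so the trough-to-peak excursion equals the target
amplitude; the a-wave is 25% of the b-wave (cosmetic — only the b-wave is
analysed).  Traces are sampled at 1 kHz for 300 ms with the flash at
50 ms.  The default intensity grid is -5.0 to 0.0 log10 μmol/m²/s in
0.5 steps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .erg import ERGTrace, WAVELENGTHS_NM, boltzmann_value
from .spectra import SpectrumCurve

__all__ = [
    "SpectrumProfile",
    "ERGTruth",
    "CohortDesign",
    "generate_spectrum",
    "generate_marking_table",
    "generate_erg_experiment",
    "generate_cohort",
    "simulate_amplitude_table",
    "default_cohort_design",
    "default_spectrum_profiles",
    "write_bundle",
]

# trace geometry (ms)
SAMPLING_KHZ = 1.0
TRACE_LEN_MS = 300.0
FLASH_ONSET_MS = 50.0
A_TROUGH_MS = 30.0   # after onset
B_PEAK_MS = 80.0     # after onset
A_SIGMA_MS = 8.0
B_SIGMA_MS = 20.0
A_TO_B_RATIO = 0.25

DEFAULT_INTENSITY_GRID = tuple(np.arange(-5.0, 0.01, 0.5))


@dataclass
class SpectrumProfile:
    """Ground truth for one synthetic reflectance curve."""

    baseline_pct: float = 5.0
    peaks: Sequence[tuple[float, float, float]] = ()  # (center_nm, amplitude_pct, sigma_nm)
    noise_sd_pct: float = 0.0
    grid: tuple[float, float, float] = (300.0, 700.0, 1.0)  # start, stop, step
    seed: int = 0

    def __post_init__(self) -> None:
        start, stop, step = self.grid
        if not (start < stop and step > 0):
            raise ValueError(f"invalid grid {self.grid}: need start < stop and step > 0")
        if self.baseline_pct < 0:
            raise ValueError("baseline_pct must be >= 0")
        for center, amp, sigma in self.peaks:
            if sigma <= 0:
                raise ValueError(f"peak at {center} nm: sigma must be > 0")
            if amp < 0:
                raise ValueError(f"peak at {center} nm: amplitude must be >= 0")
        if self.noise_sd_pct < 0:
            raise ValueError("noise_sd_pct must be >= 0")


def generate_spectrum(profile: SpectrumProfile, meta: Mapping | None = None) -> SpectrumCurve:
    """Baseline + sum of Gaussian peaks + Gaussian noise, clipped at 0.

    The generating profile is retained in the curve metadata under
    ``"truth"``.  Identical profiles (same seed) give identical curves.
    """
    start, stop, step = profile.grid
    wl = np.arange(start, stop + step / 2, step)
    r = np.full_like(wl, float(profile.baseline_pct))
    for center, amp, sigma in profile.peaks:
        r = r + amp * np.exp(-((wl - center) ** 2) / (2.0 * sigma**2))
    if profile.noise_sd_pct > 0:
        rng = np.random.default_rng(profile.seed)
        r = r + rng.normal(0.0, profile.noise_sd_pct, size=len(wl))
    r = np.clip(r, 0.0, None)
    m = dict(meta or {})
    m["truth"] = profile
    return SpectrumCurve(wl, r, m)


def generate_marking_table(
    markings: Sequence[tuple[str, str, str, tuple[float, float, float], float]],
    total_areas: Mapping[tuple[str, str], float],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build markings + surfaces tables from area *fractions*.

    ``markings`` rows are ``(frog_id, surface, label, (r, g, b),
    area_fraction)``; ``total_areas`` maps (frog_id, surface) to the
    surface total in mm².  Marking areas are fraction x total; fractions
    summing above 1 on any surface are rejected.
    """
    rows = []
    frac_sums: dict[tuple[str, str], float] = {}
    for frog, surface, label, rgb, fraction in markings:
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"{frog}/{surface}/{label}: fraction {fraction} outside [0, 1]")
        key = (frog, surface)
        if key not in total_areas:
            raise ValueError(f"no total area given for {key}")
        frac_sums[key] = frac_sums.get(key, 0.0) + fraction
        if frac_sums[key] > 1.0 + 1e-9:
            raise ValueError(
                f"{frog}/{surface}: area fractions sum to {frac_sums[key]:.3f} > 1")
        r, g, b = rgb
        rows.append({
            "frog_id": frog, "surface": surface, "marking_label": label,
            "r": float(r), "g": float(g), "b": float(b),
            "area_mm2": fraction * float(total_areas[key]),
        })
    markings_df = pd.DataFrame(
        rows, columns=["frog_id", "surface", "marking_label", "r", "g", "b", "area_mm2"])
    surfaces_df = pd.DataFrame(
        [{"frog_id": f, "surface": s, "total_area_mm2": float(a)}
         for (f, s), a in total_areas.items()],
        columns=["frog_id", "surface", "total_area_mm2"])
    return markings_df, surfaces_df


@dataclass
class ERGTruth:
    """Ground truth for one (animal, wavelength) intensity-response series."""

    animal_id: str
    wavelength_nm: int
    flash0_true: float
    tau_true: float
    max_bwave_uv: float = 120.0
    noise_sd_uv: float = 0.0
    dc_offset_uv: float = 0.0
    intensity_grid: Sequence[float] = DEFAULT_INTENSITY_GRID
    n_flashes_per_step: int = 4

    def __post_init__(self) -> None:
        if self.tau_true <= 0:
            raise ValueError("tau_true must be > 0")
        if self.max_bwave_uv <= 0:
            raise ValueError("max_bwave_uv must be > 0")
        grid = np.asarray(self.intensity_grid, dtype=float)
        if grid.size == 0:
            raise ValueError("intensity grid is empty")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("intensity grid must be strictly increasing")
        self.intensity_grid = tuple(float(v) for v in grid)


def _waveform_template(time_ms: np.ndarray, onset_ms: float) -> np.ndarray:
    """Unit template: a-trough then b-peak, trough-to-peak excursion 1."""
    t = time_ms - onset_ms
    a = -A_TO_B_RATIO * np.exp(-((t - A_TROUGH_MS) ** 2) / (2 * A_SIGMA_MS**2))
    b = np.exp(-((t - B_PEAK_MS) ** 2) / (2 * B_SIGMA_MS**2))
    w = np.where(t >= 0, a + b, 0.0)
    span = w.max() - w.min()
    return w / span


def generate_erg_experiment(
    truth: ERGTruth,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    artifact_steps: Sequence[float] = (),
) -> list[ERGTrace]:
    """Simulate the flash series for one (animal, wavelength).

    Returns 4 no-light traces (DC offset + noise only) followed by
    ``n_flashes_per_step`` traces per intensity, whose noiseless
    trough-to-peak b-wave amplitude is ``max_bwave_uv x Boltzmann(flash)``.
    For each intensity listed in ``artifact_steps`` the first trace of the
    step receives 10x the nominal noise, to exercise artifact rejection
    (requires ``noise_sd_uv > 0`` to have any effect).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n_samples = int(TRACE_LEN_MS * SAMPLING_KHZ) + 1
    time_ms = np.arange(n_samples) / SAMPLING_KHZ
    template = _waveform_template(time_ms, FLASH_ONSET_MS)

    def noise(sd: float) -> np.ndarray:
        return rng.normal(0.0, sd, size=n_samples) if sd > 0 else np.zeros(n_samples)

    traces: list[ERGTrace] = []
    for _ in range(4):
        traces.append(ERGTrace(
            time_ms, truth.dc_offset_uv + noise(truth.noise_sd_uv),
            truth.animal_id, None, None, FLASH_ONSET_MS, no_light=True))
    artifact_set = {round(float(s), 9) for s in artifact_steps}
    for flash in truth.intensity_grid:
        amp = truth.max_bwave_uv * boltzmann_value(flash, truth.flash0_true, truth.tau_true)
        for k in range(truth.n_flashes_per_step):
            sd = truth.noise_sd_uv
            if k == 0 and round(float(flash), 9) in artifact_set:
                sd = 10.0 * truth.noise_sd_uv
            traces.append(ERGTrace(
                time_ms, amp * template + truth.dc_offset_uv + noise(sd),
                truth.animal_id, truth.wavelength_nm, float(flash),
                FLASH_ONSET_MS))
    return traces


@dataclass
class CohortDesign:
    """Study design for a synthetic cohort, mirroring the field study's shape.

    ``groups`` lists (label, n_female, n_male); ``base_flash0`` gives the
    true half-max intensity per wavelength for every group, on top of
    which ``effect_map`` applies per-(group, wavelength) shifts (negative
    = more sensitive).  Between-animal variation enters as a Gaussian
    shift of flash0 with SD ``animal_sd``.
    """

    groups: Sequence[tuple[str, int, int]]
    wavelengths_nm: Sequence[int] = WAVELENGTHS_NM
    base_flash0: Mapping[int, float] | float = -2.5
    base_tau: float = 0.4
    effect_map: Mapping[tuple[str, int], float] = field(default_factory=dict)
    animal_sd: float = 0.15
    max_bwave_range_uv: tuple[float, float] = (80.0, 200.0)
    intensity_grid: Sequence[float] = DEFAULT_INTENSITY_GRID
    n_flashes_per_step: int = 4

    def __post_init__(self) -> None:
        for label, nf, nm in self.groups:
            if nf < 0 or nm < 0:
                raise ValueError(f"group {label}: negative sample size")
        for wl in self.wavelengths_nm:
            if wl not in WAVELENGTHS_NM:
                raise ValueError(f"unknown stimulus wavelength {wl} nm")
        for (group, wl) in self.effect_map:
            if wl not in self.wavelengths_nm:
                raise ValueError(f"effect map references untested wavelength {wl} nm")

    def flash0_at(self, group: str, wavelength_nm: int) -> float:
        base = (self.base_flash0[wavelength_nm]
                if isinstance(self.base_flash0, Mapping) else float(self.base_flash0))
        return base + self.effect_map.get((group, wavelength_nm), 0.0)


def generate_cohort(design: CohortDesign, seed: int = 0) -> pd.DataFrame:
    """One ground-truth row per animal per wavelength, reproducible by seed.

    Columns: animal_id, group, sex, wavelength_nm, flash0_true, tau_true,
    max_bwave_uv.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for label, n_female, n_male in design.groups:
        sexes = ["F"] * n_female + ["M"] * n_male
        for i, sex in enumerate(sexes):
            animal = f"{label}-{i + 1:02d}"
            offset = rng.normal(0.0, design.animal_sd) if design.animal_sd > 0 else 0.0
            max_b = rng.uniform(*design.max_bwave_range_uv)
            for wl in design.wavelengths_nm:
                rows.append({
                    "animal_id": animal, "group": label, "sex": sex,
                    "wavelength_nm": int(wl),
                    "flash0_true": design.flash0_at(label, wl) + offset,
                    "tau_true": design.base_tau,
                    "max_bwave_uv": max_b,
                })
    return pd.DataFrame(rows)


def simulate_amplitude_table(
    truths: pd.DataFrame,
    intensity_grid: Sequence[float] = DEFAULT_INTENSITY_GRID,
    noise_sd_rel: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Pre-extracted b-wave amplitude table from cohort ground truth.

    For each truth row and each intensity, ``bwave_uv = max_bwave_uv x
    (Boltzmann(flash) + N(0, noise_sd_rel))`` floored at 0 (a trough-to-
    peak measurement cannot be negative).  This is the fast, trace-free
    route into the analysis pipeline.
    """
    rng = np.random.default_rng(seed)
    grid = np.asarray(intensity_grid, dtype=float)
    rows = []
    for rec in truths.itertuples(index=False):
        rel = boltzmann_value(grid, rec.flash0_true, rec.tau_true)
        if noise_sd_rel > 0:
            rel = rel + rng.normal(0.0, noise_sd_rel, size=len(grid))
        amp = np.clip(rec.max_bwave_uv * rel, 0.0, None)
        for flash, a in zip(grid, amp):
            rows.append({
                "animal_id": rec.animal_id, "group": rec.group, "sex": rec.sex,
                "wavelength_nm": rec.wavelength_nm,
                "log_intensity": float(flash), "bwave_uv": float(a),
            })
    return pd.DataFrame(rows)


def default_cohort_design() -> CohortDesign:
    """Two aposematic morphs, 11 animals each (7F+4M and 6F+5M).

    The second morph carries a -0.5 log-unit sensitivity advantage at 450
    and 550 nm, on a base spectral profile whose most sensitive wavelength
    is 600 nm — so the two morphs' tuning-curve minima land at 600 nm and
    550 nm respectively.
    """
    base = {350: -2.2, 400: -2.4, 450: -2.5, 500: -2.6,
            550: -2.7, 600: -2.9, 650: -2.6}
    return CohortDesign(
        groups=[("Cemetery", 7, 4), ("Popa", 6, 5)],
        wavelengths_nm=WAVELENGTHS_NM,
        base_flash0=base,
        base_tau=0.4,
        effect_map={("Popa", 450): -0.5, ("Popa", 550): -0.5},
    )


def default_spectrum_profiles() -> dict[str, SpectrumProfile]:
    """Dorsal reflectance profiles for the two default morphs.

    One morph peaks at 642 nm with a broad band (sigma 84 nm, matching a
    FWHM near 198 nm), the other at 560 nm with a narrower band.
    """
    return {
        "Cemetery": SpectrumProfile(baseline_pct=4.0,
                                    peaks=[(642.0, 55.0, 84.0)],
                                    noise_sd_pct=1.0),
        "Popa": SpectrumProfile(baseline_pct=4.0,
                                peaks=[(560.0, 50.0, 40.0)],
                                noise_sd_pct=1.0),
    }


def write_bundle(
    out_dir: str | Path,
    design: CohortDesign | None = None,
    seed: int = 0,
    n_spectra_per_group: int = 5,
    with_traces: bool = False,
    trace_noise_sd_uv: float = 5.0,
    dc_offset_uv: float = 5.0,
) -> Path:
    """Emit a complete synthetic study directory readable by the pipeline.

    Layout: ``spectra/`` (per-specimen dorsal reflectance CSVs + metadata
    sidecars), ``markings.csv`` + ``surfaces.csv``, ``erg/`` (either an
    ``amplitudes.csv`` table or, with ``with_traces``, per-animal
    per-wavelength trace directories with a flash manifest), and
    ``truth.json`` recording every generator parameter.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if design is None:
        design = default_cohort_design()
    rng = np.random.default_rng(seed)

    # --- spectra ---
    profiles = default_spectrum_profiles()
    spectra_dir = out / "spectra"
    spectra_dir.mkdir(exist_ok=True)
    group_labels = [g[0] for g in design.groups]
    for label in group_labels:
        profile = profiles.get(label, SpectrumProfile(
            baseline_pct=5.0, peaks=[(500.0, 40.0, 50.0)], noise_sd_pct=1.0))
        for i in range(n_spectra_per_group):
            p = SpectrumProfile(profile.baseline_pct, profile.peaks,
                                profile.noise_sd_pct, profile.grid,
                                seed=int(rng.integers(0, 2**31 - 1)))
            meta = {"specimen_id": f"{label}-{i + 1:02d}", "morph": label,
                    "region": "dorsal"}
            curve = generate_spectrum(p, meta)
            stem = spectra_dir / f"{label}-{i + 1:02d}_dorsal.csv"
            pd.DataFrame({"wavelength_nm": curve.wavelength_nm,
                          "reflectance_pct": curve.reflectance_pct}).to_csv(stem, index=False)
            stem.with_suffix(".csv.meta.json").write_text(json.dumps(meta))

    # --- markings: one bright marking + dark background per frog ---
    marking_rows, areas = [], {}
    for label, n_female, n_male in design.groups:
        bright = tuple(float(c) for c in rng.uniform(120, 255, size=3))
        dark = tuple(float(c) for c in rng.uniform(0, 60, size=3))
        for i in range(n_female + n_male):
            frog = f"{label}-{i + 1:02d}"
            for surface in ("dorsal", "lateral"):
                total = float(rng.uniform(80, 160))
                frac = float(rng.uniform(0.3, 0.7))
                areas[(frog, surface)] = total
                marking_rows.append((frog, surface, "bright", bright, frac))
                marking_rows.append((frog, surface, "background", dark, 1.0 - frac))
    markings_df, surfaces_df = generate_marking_table(marking_rows, areas)
    markings_df.to_csv(out / "markings.csv", index=False)
    surfaces_df.to_csv(out / "surfaces.csv", index=False)

    # --- ERG ---
    truths = generate_cohort(design, seed=int(rng.integers(0, 2**31 - 1)))
    erg_dir = out / "erg"
    erg_dir.mkdir(exist_ok=True)
    if with_traces:
        for rec in truths.itertuples(index=False):
            truth = ERGTruth(rec.animal_id, rec.wavelength_nm, rec.flash0_true,
                             rec.tau_true, rec.max_bwave_uv,
                             noise_sd_uv=trace_noise_sd_uv,
                             dc_offset_uv=dc_offset_uv,
                             intensity_grid=design.intensity_grid,
                             n_flashes_per_step=design.n_flashes_per_step)
            tdir = erg_dir / rec.animal_id / str(rec.wavelength_nm)
            tdir.mkdir(parents=True, exist_ok=True)
            traces = generate_erg_experiment(
                truth, rng=np.random.default_rng(int(rng.integers(0, 2**31 - 1))))
            manifest = []
            for j, tr in enumerate(traces):
                name = f"trace_{j:03d}.csv"
                pd.DataFrame({"time_ms": tr.time_ms,
                              "voltage_uv": tr.voltage_uv}).to_csv(tdir / name, index=False)
                manifest.append({
                    "file": name, "animal_id": tr.animal_id,
                    "wavelength_nm": tr.wavelength_nm,
                    "log_intensity": tr.log_intensity,
                    "flash_onset_ms": tr.flash_onset_ms,
                    "no_light": tr.no_light,
                })
            (tdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    else:
        amplitudes = simulate_amplitude_table(
            truths, design.intensity_grid, noise_sd_rel=0.05,
            seed=int(rng.integers(0, 2**31 - 1)))
        amplitudes.to_csv(erg_dir / "amplitudes.csv", index=False)

    truth_json = {
        "seed": seed,
        "design": {
            "groups": [list(g) for g in design.groups],
            "wavelengths_nm": list(design.wavelengths_nm),
            "base_flash0": (dict(design.base_flash0)
                            if isinstance(design.base_flash0, Mapping)
                            else design.base_flash0),
            "base_tau": design.base_tau,
            "effect_map": {f"{g}:{w}": v for (g, w), v in design.effect_map.items()},
            "animal_sd": design.animal_sd,
            "intensity_grid": list(design.intensity_grid),
        },
        "truths": truths.to_dict(orient="records"),
    }
    (out / "truth.json").write_text(json.dumps(truth_json, indent=1))
    return out
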