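"""Area-scaled reflectance scores from calibrated-photograph markings.

Each distinct skin marking on a photographed surface (dorsal or lateral)
contributes its total reflectance, the sum R+G+B of its calibrated mean
color, weighted by the fraction of the surface it occupies:

    score(surface) = sum_markings (R+G+B) * area_mm2 / total_area_mm2

and a frog's total is dorsal + lateral.  Area fractions are computed from
mm^2 measurements (the pixel-to-mm conversion from the photographed scale
bar is the caller's responsibility), RGB values are assumed already
color-calibrated, and unmarked skin contributes zero.  A per-surface score
is therefore bounded by 765 (= 3 x 255) when fractions sum to at most 1.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SURFACES",
    "marking_total_reflectance",
    "region_mean_rgb",
    "scaled_reflectance",
]

SURFACES = ("dorsal", "lateral")

#: tolerated excess of summed marking areas over the measured surface total
AREA_TOLERANCE = 0.01

MARKING_COLUMNS = ["frog_id", "surface", "marking_label", "r", "g", "b", "area_mm2"]
SURFACE_COLUMNS = ["frog_id", "surface", "total_area_mm2"]


def marking_total_reflectance(rgb: Sequence[float]) -> float:
    """Total reflectance (a.u.) of one marking: R + G + B.

    Channels must lie in [0, 255].
    """
    r, g, b = (float(c) for c in rgb)
    for name, c in zip("RGB", (r, g, b)):
        if not 0.0 <= c <= 255.0:
            raise ValueError(f"channel {name}={c} outside [0, 255]")
    return r + g + b


def region_mean_rgb(pixels: np.ndarray, mask: np.ndarray) -> tuple[float, float, float]:
    """Unrounded per-channel mean color over the masked pixels of a raster.

    ``pixels`` is (H, W, 3); ``mask`` is a (H, W) boolean raster of the
    same height and width selecting the marking's pixels.
    """
    pixels = np.asarray(pixels, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError("pixels must be an (H, W, 3) array")
    if mask.shape != pixels.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match raster {pixels.shape[:2]}"
        )
    if not mask.any():
        raise ValueError("empty mask: no pixels selected")
    sel = pixels[mask]
    return tuple(float(v) for v in sel.mean(axis=0))


def _validate_markings(markings: pd.DataFrame) -> pd.DataFrame:
    missing = set(MARKING_COLUMNS) - set(markings.columns)
    if missing:
        raise ValueError(f"markings table missing columns: {sorted(missing)}")
    m = markings.copy()
    for col in ("r", "g", "b"):
        bad = (m[col] < 0) | (m[col] > 255)
        if bad.any():
            row = m.index[bad][0]
            raise ValueError(f"marking row {row}: channel {col}={m.loc[row, col]} outside [0, 255]")
    if (m["area_mm2"] < 0).any():
        row = m.index[m["area_mm2"] < 0][0]
        raise ValueError(f"marking row {row}: negative area")
    return m


def scaled_reflectance(markings: pd.DataFrame, surfaces: pd.DataFrame) -> pd.DataFrame:
    """Per-surface and per-frog area-scaled reflectance scores.

    Parameters
    ----------
    markings
        Columns ``frog_id, surface, marking_label, r, g, b, area_mm2``;
        one row per distinct marking.  A frog/surface absent from this
        table but present in ``surfaces`` scores 0.
    surfaces
        Columns ``frog_id, surface, total_area_mm2`` with total > 0.

    Returns
    -------
    DataFrame with one row per (frog_id, surface) holding
    ``scaled_reflectance_au`` plus a ``frog_total_au`` column repeating the
    frog's dorsal + lateral sum.

    Raises
    ------
    ValueError
        if a marking references a surface with no surface record, or the
        summed marking areas exceed the surface total by more than 1%.
    """
    missing = set(SURFACE_COLUMNS) - set(surfaces.columns)
    if missing:
        raise ValueError(f"surfaces table missing columns: {sorted(missing)}")
    if (surfaces["total_area_mm2"] <= 0).any():
        raise ValueError("total_area_mm2 must be positive")
    if surfaces.duplicated(["frog_id", "surface"]).any():
        raise ValueError("duplicate (frog_id, surface) in surfaces table")
    m = _validate_markings(markings)

    totals = surfaces.set_index(["frog_id", "surface"])["total_area_mm2"]
    scores = {key: 0.0 for key in totals.index}
    if len(m):
        for (frog, surf), grp in m.groupby(["frog_id", "surface"], sort=False):
            key = (frog, surf)
            if key not in totals.index:
                raise ValueError(f"no surface record for frog {frog!r} surface {surf!r}")
            total = totals.loc[key]
            covered = grp["area_mm2"].sum()
            if covered > total * (1 + AREA_TOLERANCE):
                raise ValueError(
                    f"frog {frog!r} {surf}: marking areas ({covered:g} mm^2) exceed "
                    f"surface total ({total:g} mm^2) by more than {AREA_TOLERANCE:.0%}"
                )
            rgb_sum = grp[["r", "g", "b"]].sum(axis=1)
            scores[key] = float((rgb_sum * grp["area_mm2"] / total).sum())

    out = pd.DataFrame(
        [(f, s, v) for (f, s), v in scores.items()],
        columns=["frog_id", "surface", "scaled_reflectance_au"],
    ).sort_values(["frog_id", "surface"], ignore_index=True)
    frog_totals = out.groupby("frog_id")["scaled_reflectance_au"].transform("sum")
    out["frog_total_au"] = frog_totals
    return out
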