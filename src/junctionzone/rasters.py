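"""Raster containers for en-face OCT data.

All rasters live on a square, fovea-centered angular grid: the value at
pixel (row, col) refers to the A-scan position at
``(row - (H-1)/2, col - (W-1)/2) * pixel_pitch_deg`` degrees from the
foveal center.  Thickness maps carry micrometres, z-score maps carry
dimensionless standardized units, lesion masks are boolean.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

LAYERS = ("ONL", "IS", "OS")


@dataclass
class ThicknessMap:
    """2D en-face thickness raster (µm) for one retinal layer.

    Parameters
    ----------
    layer : str
        One of ``ONL``, ``IS``, ``OS``.
    grid : ndarray
        Square 2D array of thicknesses in µm; non-negative and finite.
    pixel_pitch_deg : float
        Angular pixel size in degrees per pixel (isotropic).
    laterality : str
        ``"R"`` or ``"L"``; left-eye maps are mirrored to right-eye
        orientation before any normative comparison.
    """

    layer: str
    grid: np.ndarray
    pixel_pitch_deg: float
    laterality: str = "R"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError("thickness grid must be a square 2D array")
        if self.pixel_pitch_deg <= 0:
            raise ValueError("pixel_pitch_deg must be positive")
        if not np.all(np.isfinite(self.grid)) or np.any(self.grid < 0):
            raise ValueError("thickness values must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass
class LesionMask:
    """Binary RPE-atrophy (GA) mask on the same raster as its companion maps."""

    grid: np.ndarray
    pixel_pitch_deg: float
    visit_month: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError("lesion mask must be a square 2D array")
        if self.pixel_pitch_deg <= 0:
            raise ValueError("pixel_pitch_deg must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def n_pixels(self) -> int:
        return int(self.grid.sum())


@dataclass
class ZScoreMap:
    """Standardized thickness raster: (observed − age-adjusted mean) / local SD."""

    layer: str
    grid: np.ndarray
    pixel_pitch_deg: float
    laterality: str = "R"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError("z-score grid must be a square 2D array")


def write_thickness_tiff(path: str | Path, tmap: ThicknessMap) -> None:
    tifffile.imwrite(str(path), tmap.grid.astype(np.float32))


def read_thickness_tiff(
    path: str | Path, layer: str, pixel_pitch_deg: float, laterality: str = "R"
) -> ThicknessMap:
    grid = tifffile.imread(str(path))
    return ThicknessMap(layer=layer, grid=grid, pixel_pitch_deg=pixel_pitch_deg,
                        laterality=laterality)


def write_mask_tiff(path: str | Path, mask: LesionMask) -> None:
    tifffile.imwrite(str(path), (mask.grid.astype(np.uint8) * 255))


def read_mask_tiff(path: str | Path, pixel_pitch_deg: float, visit_month: int = 0) -> LesionMask:
    grid = tifffile.imread(str(path)) > 0
    return LesionMask(grid=grid, pixel_pitch_deg=pixel_pitch_deg, visit_month=visit_month)
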