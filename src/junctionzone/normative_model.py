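"""Age-adjusted, location-specific normative model and z-score transform.

Photoreceptor laminae thickness varies strongly with retinal topography
(e.g. the foveal ONL peak) and declines with age.  To compare thickness
at *traveling* contour-lines across visits, maps are standardized
pixelwise against a reference set of non-atrophic eyes:

    z(x) = (t(x) − (β₀(x) + β₁(x)·age)) / σ(x)

with a per-pixel linear age model and a per-pixel residual SD (assumed
homoscedastic in age).  Left eyes are mirrored to right-eye orientation
before fitting and standardization so that nasal/temporal asymmetry is
preserved in the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .rasters import ThicknessMap, ZScoreMap

#: Default lower bound on the residual SD map (µm), guarding the division.
SD_FLOOR_UM = 1.0


@dataclass
class LayerNorm:
    """Per-pixel normative fit for one layer: t ≈ intercept + slope·age ± sd."""

    intercept_map: np.ndarray  # µm at age 0
    age_slope_map: np.ndarray  # µm / year
    sd_map: np.ndarray         # µm, residual SD floored at sd_floor


@dataclass
class NormativeModel:
    """Location-specific normative reference for all layers on one raster."""

    layers: dict[str, LayerNorm]
    pixel_pitch_deg: float
    reference_age_range: tuple[float, float]
    sd_floor: float = SD_FLOOR_UM

    def mean_map(self, layer: str, age: float) -> np.ndarray:
        ln = self.layers[layer]
        return ln.intercept_map + ln.age_slope_map * age

    def save(self, directory: str | Path) -> None:
        """Serialize as per-layer TIFF rasters plus a YAML metadata file."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name, ln in self.layers.items():
            tifffile.imwrite(d / f"{name}_intercept.tif", ln.intercept_map.astype(np.float32))
            tifffile.imwrite(d / f"{name}_age_slope.tif", ln.age_slope_map.astype(np.float32))
            tifffile.imwrite(d / f"{name}_sd.tif", ln.sd_map.astype(np.float32))
        meta = {
            "layers": sorted(self.layers),
            "pixel_pitch_deg": float(self.pixel_pitch_deg),
            "reference_age_range": [float(a) for a in self.reference_age_range],
            "sd_floor": float(self.sd_floor),
        }
        (d / "normative_model.yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def load(cls, directory: str | Path) -> "NormativeModel":
        d = Path(directory)
        meta = yaml.safe_load((d / "normative_model.yaml").read_text())
        layers = {}
        for name in meta["layers"]:
            layers[name] = LayerNorm(
                intercept_map=tifffile.imread(d / f"{name}_intercept.tif").astype(np.float64),
                age_slope_map=tifffile.imread(d / f"{name}_age_slope.tif").astype(np.float64),
                sd_map=tifffile.imread(d / f"{name}_sd.tif").astype(np.float64),
            )
        return cls(
            layers=layers,
            pixel_pitch_deg=meta["pixel_pitch_deg"],
            reference_age_range=tuple(meta["reference_age_range"]),
            sd_floor=meta["sd_floor"],
        )


def _oriented(grid: np.ndarray, laterality: str) -> np.ndarray:
    """Mirror left-eye rasters to right-eye orientation (horizontal flip)."""
    return np.fliplr(grid) if laterality == "L" else grid


def fit_normative(
    maps: dict[str, list[ThicknessMap]] | list[ThicknessMap],
    ages: np.ndarray,
    sd_floor: float = SD_FLOOR_UM,
) -> NormativeModel:
    """Fit the per-pixel linear age model from a normative map set.

    Parameters
    ----------
    maps : dict or list
        Either ``{layer: [ThicknessMap, ...]}`` with one map per
        reference eye per layer, or a flat list for a single layer.
        All maps must share one raster geometry.
    ages : array-like
        Age (years) of each reference eye, same order as the maps.
    sd_floor : float
        Lower bound on the residual SD map in µm.

    Notes
    -----
    Ordinary least squares per pixel, ``t ~ 1 + age``; the SD map is the
    residual standard deviation (ddof = 2), floored at ``sd_floor``.
    Requires at least 3 eyes and non-constant ages.
    """
    if not isinstance(maps, dict):
        maps = {maps[0].layer: list(maps)}
    ages = np.asarray(ages, dtype=float)
    if ages.size < 3:
        raise ValueError("need at least 3 reference eyes to fit the age model")
    if np.ptp(ages) == 0:
        raise ValueError("reference ages are constant; age slope is unidentifiable")

    first = next(iter(maps.values()))[0]
    shape, pitch = first.shape, first.pixel_pitch_deg
    A = np.column_stack([np.ones_like(ages), ages])
    pinv = np.linalg.pinv(A)

    layers = {}
    for layer, layer_maps in maps.items():
        if len(layer_maps) != ages.size:
            raise ValueError(f"{layer}: number of maps does not match number of ages")
        stack = np.empty((ages.size, *shape))
        for i, m in enumerate(layer_maps):
            if m.shape != shape or m.pixel_pitch_deg != pitch:
                raise ValueError("normative maps have mismatched raster geometry")
            stack[i] = _oriented(m.grid, m.laterality)
        Y = stack.reshape(ages.size, -1)
        beta = pinv @ Y
        resid = Y - A @ beta
        dof = max(ages.size - 2, 1)
        sd = np.sqrt((resid**2).sum(axis=0) / dof)
        layers[layer] = LayerNorm(
            intercept_map=beta[0].reshape(shape),
            age_slope_map=beta[1].reshape(shape),
            sd_map=np.maximum(sd.reshape(shape), sd_floor),
        )
    return NormativeModel(
        layers=layers,
        pixel_pitch_deg=pitch,
        reference_age_range=(float(ages.min()), float(ages.max())),
        sd_floor=sd_floor,
    )


def standardize(tmap: ThicknessMap, age: float, model: NormativeModel) -> ZScoreMap:
    """Transform a thickness map to z-score units against the normative model.

    z(x) = (t(x) − (intercept(x) + slope(x)·age)) / sd(x), pixelwise, in
    right-eye orientation internally; the result is returned in the
    input's native orientation.  Ages outside the reference range raise
    an extrapolation warning, not an error.
    """
    if tmap.layer not in model.layers:
        raise KeyError(f"layer {tmap.layer!r} not present in the normative model")
    ln = model.layers[tmap.layer]
    if tmap.shape != ln.sd_map.shape or tmap.pixel_pitch_deg != model.pixel_pitch_deg:
        raise ValueError("map geometry does not match the normative model raster")
    lo, hi = model.reference_age_range
    if not (lo <= age <= hi):
        warnings.warn(
            f"age {age:.1f} outside normative reference range [{lo:.1f}, {hi:.1f}]; "
            "extrapolating the age model",
            stacklevel=2,
        )
    grid = _oriented(tmap.grid.astype(np.float64), tmap.laterality)
    z = (grid - (ln.intercept_map + ln.age_slope_map * age)) / ln.sd_map
    z = _oriented(z, tmap.laterality)  # back to native orientation
    return ZScoreMap(layer=tmap.layer, grid=z, pixel_pitch_deg=tmap.pixel_pitch_deg,
                     laterality=tmap.laterality)
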