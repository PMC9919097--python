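"""Soil/plant thermal map assembly and leaf-temperature-map fusion.

The scanned grid of object temperatures (one IR reading per 20 mm cell)
is bilinearly upsampled to a common geometry, the plant mask is
nearest-neighbour resampled to the same geometry, and their pixel-wise
crossing keeps temperature only where there is plant: the Leaf
Temperature Map (LTM).  Non-plant pixels carry NaN, an explicit sentinel
distinct from 0 degC.

Coordinate convention: rasters are row-major with the origin at the
top-left and 0-based indices; grid cell (i, j) is centered at
((i + 0.5) * cell, (j + 0.5) * cell) mm from the grid origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

logger = logging.getLogger(__name__)

__all__ = [
    "ThermalGrid",
    "LeafTemperatureMap",
    "ValidationReport",
    "IncompleteScanError",
    "assemble_grid",
    "resize_bilinear",
    "resize_mask",
    "build_ltm",
    "validate_against_reference",
]

#: Width x height of the fused leaf temperature map, i.e. (H, W) = (620, 1280).
DEFAULT_LTM_DIMS = (620, 1280)


class IncompleteScanError(ValueError):
    """A scan is missing grid cells; ``missing`` lists the absent indices."""

    def __init__(self, missing):
        self.missing = list(missing)
        preview = ", ".join(map(str, self.missing[:10]))
        more = "" if len(self.missing) <= 10 else f" (+{len(self.missing) - 10} more)"
        super().__init__(f"scan is missing {len(self.missing)} cells: {preview}{more}")


@dataclass
class ThermalGrid:
    """Object-temperature raster from one scan.

    ``values`` has shape (ny, nx) with values[j, i] the reading of cell
    (i, j); ``cell_size`` in mm; ``origin_mm`` the (x, y) of the grid's
    top-left corner on the bench; ``t_air``/``rh`` the ambient record at
    scan time.
    """

    values: np.ndarray
    cell_size: float = 20.0
    origin_mm: tuple = (0.0, 0.0)
    t_air: float = float("nan")
    rh: float = float("nan")
    timestamp: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (ny, nx)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("object temperatures must be finite")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path) -> None:
        import pandas as pd

        jj, ii = np.mgrid[0 : self.ny, 0 : self.nx]
        pd.DataFrame(
            {
                "x_index": ii.ravel(),
                "y_index": jj.ravel(),
                "x_mm": self.origin_mm[0] + (ii.ravel() + 0.5) * self.cell_size,
                "y_mm": self.origin_mm[1] + (jj.ravel() + 0.5) * self.cell_size,
                "T_O": self.values.ravel(),
                "T_A": self.t_air,
                "RH": self.rh,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, cell_size: float = 20.0) -> "ThermalGrid":
        import pandas as pd

        df = pd.read_csv(path)
        readings = list(
            zip(df["x_index"], df["y_index"], df["T_O"], df["T_A"], df["RH"])
        )
        return assemble_grid(readings, cell_size=cell_size)


def assemble_grid(readings, cell_size: float = 20.0, origin_mm=(0.0, 0.0)) -> ThermalGrid:
    """Build a ThermalGrid from (x_index, y_index, T_O, T_A, RH) readings.

    The indices must form a complete 0-based rectangle with no
    duplicates; gaps raise :class:`IncompleteScanError` naming the
    absent cells.
    """
    readings = list(readings)
    if not readings:
        raise ValueError("no readings supplied")
    seen = {}
    for x, y, t_o, t_a, rh in readings:
        key = (int(x), int(y))
        if key in seen:
            raise ValueError(f"duplicate reading at index {key}")
        seen[key] = (float(t_o), float(t_a), float(rh))

    nx = max(k[0] for k in seen) + 1
    ny = max(k[1] for k in seen) + 1
    missing = [
        (i, j) for j in range(ny) for i in range(nx) if (i, j) not in seen
    ]
    if missing:
        raise IncompleteScanError(missing)

    values = np.empty((ny, nx))
    for (i, j), (t_o, _, _) in seen.items():
        values[j, i] = t_o
    t_air = float(np.mean([v[1] for v in seen.values()]))
    rh = float(np.mean([v[2] for v in seen.values()]))
    return ThermalGrid(
        values=values, cell_size=cell_size, origin_mm=tuple(origin_mm),
        t_air=t_air, rh=rh,
    )


def _target_coords(n_src: int, n_tgt: int) -> np.ndarray:
    # corner-aligned: first/last target samples coincide with source corners
    if n_tgt == 1:
        return np.zeros(1)
    return np.arange(n_tgt) * (n_src - 1) / (n_tgt - 1)


def resize_bilinear(raster, target_dims) -> np.ndarray:
    """Bilinear resize with corner-aligned coordinates.

    Output values are convex combinations of the four surrounding source
    samples and therefore never exceed the source extrema.
    """
    arr = np.asarray(raster, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("source raster must be at least 2 x 2")
    ht, wt = target_dims
    if ht < 1 or wt < 1:
        raise ValueError("target dims must be at least 1 x 1")
    if (ht, wt) == arr.shape:
        return arr.copy()
    interp = RegularGridInterpolator(
        (np.arange(arr.shape[0]), np.arange(arr.shape[1])), arr, method="linear"
    )
    rr = _target_coords(arr.shape[0], ht)
    cc = _target_coords(arr.shape[1], wt)
    grid = np.stack(np.meshgrid(rr, cc, indexing="ij"), axis=-1)
    return interp(grid)


def resize_mask(mask, target_dims) -> np.ndarray:
    """Nearest-neighbour resize of a binary mask; output stays binary."""
    arr = np.asarray(mask)
    if not set(np.unique(arr)) <= {0, 1}:
        raise ValueError("mask must be binary")
    ht, wt = target_dims
    if ht < 1 or wt < 1:
        raise ValueError("target dims must be at least 1 x 1")
    rows = np.rint(_target_coords(arr.shape[0], ht)).astype(int)
    cols = np.rint(_target_coords(arr.shape[1], wt)).astype(int)
    return arr[np.ix_(rows, cols)].astype(np.uint8)


@dataclass
class LeafTemperatureMap:
    """Plant-only temperature raster; NaN marks non-plant pixels."""

    values: np.ndarray
    source_cell_size: float = 20.0
    mask_provenance: str = "predicted"
    t_air: float = float("nan")
    rh: float = float("nan")

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")

    @property
    def plant_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n_plant_pixels(self) -> int:
        return int(self.plant_mask.sum())

    def to_csv(self, path) -> None:
        np.savetxt(path, self.values, fmt="%.6f", delimiter=",")

    def save_preview(self, path, cmap: str = "inferno") -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 4))
        im = ax.imshow(self.values, cmap=cmap)
        fig.colorbar(im, ax=ax, label="T_L (degC)")
        ax.set_axis_off()
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)


def build_ltm(
    grid: ThermalGrid,
    mask,
    target_dims=DEFAULT_LTM_DIMS,
    mask_provenance: str = "predicted",
) -> LeafTemperatureMap:
    """Fuse a thermal grid with a plant mask into a Leaf Temperature Map.

    The thermal raster is bilinearly resized and the mask
    nearest-neighbour resized to ``target_dims``; output pixels hold the
    thermal value where the resized mask is 1 and NaN elsewhere.
    """
    thermal = resize_bilinear(grid.values, target_dims)
    m = resize_mask(mask, target_dims)
    out = np.where(m == 1, thermal, np.nan)
    return LeafTemperatureMap(
        values=out,
        source_cell_size=grid.cell_size,
        mask_provenance=mask_provenance,
        t_air=grid.t_air,
        rh=grid.rh,
    )


@dataclass
class ValidationReport:
    """Pixel-wise comparison of a sensor-derived LTM against a reference.

    Per-pixel relative error (S - C)/C; the general mean error is the
    arithmetic mean of the per-pixel errors, and the mean standard error
    is sd(errors)/sqrt(n).  The mean absolute difference in degC is
    reported alongside.
    """

    errors: np.ndarray = field(repr=False)
    general_mean_error: float
    mean_standard_error: float
    mean_abs_difference_c: float
    n: int
    n_excluded_zero_reference: int = 0

    def to_dict(self) -> dict:
        return {
            "general_mean_error": self.general_mean_error,
            "mean_standard_error": self.mean_standard_error,
            "mean_abs_difference_c": self.mean_abs_difference_c,
            "n": self.n,
            "n_excluded_zero_reference": self.n_excluded_zero_reference,
        }


def validate_against_reference(ltm: LeafTemperatureMap, reference) -> ValidationReport:
    """Compare LTM plant pixels S against a reference raster C.

    Only non-null (plant) pixels are compared; pixels where the
    reference is exactly 0 degC are excluded from the relative error
    with a logged count (the ratio is undefined there).
    """
    ref = np.asarray(reference, dtype=float)
    if ref.shape != ltm.values.shape:
        raise ValueError(
            f"shape mismatch: LTM {ltm.values.shape} vs reference {ref.shape}"
        )
    sel = ltm.plant_mask
    s = ltm.values[sel]
    c = ref[sel]
    nonzero = c != 0.0
    n_excl = int((~nonzero).sum())
    if n_excl:
        logger.warning(
            "excluded %d plant pixels with zero reference temperature", n_excl
        )
    s, c = s[nonzero], c[nonzero]
    if s.size == 0:
        raise ValueError("no comparable plant pixels")
    errors = (s - c) / c
    sem = float(errors.std(ddof=1) / np.sqrt(errors.size)) if errors.size > 1 else 0.0
    return ValidationReport(
        errors=errors,
        general_mean_error=float(errors.mean()),
        mean_standard_error=sem,
        mean_abs_difference_c=float(np.abs(s - c).mean()),
        n=int(errors.size),
        n_excluded_zero_reference=n_excl,
    )
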