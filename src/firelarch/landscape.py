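"""Landscape rasters and the two-level simulation grid.

The simulated area is a square of planar meters with two grids:

* a coarse grid (default 90 m, the DEM resolution) holding elevation, slope,
  a topographic wetness index (TWI) and a water mask, and
* a fine 0.2 m sub-grid holding per-cell litter height, active-layer depth,
  ground seed counts per species, and the intensity of the last fire.

The fine grid tiles the coarse grid exactly; any coarse resolution whose
ratio to the fine resolution is an integer is accepted, which allows
desk-scale runs (e.g. 11 coarse cells at 9 m = 99 x 99 m) alongside the
full 990 x 990 m configuration.

Rasters are read and written as ESRI ASCII grids (one file per layer).
Coordinates are continuous (x, y) in meters with the origin at the
south-west corner; a cell spans the half-open interval
[i*res, (i+1)*res).  Array layout is row 0 = southern row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Landscape",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_landscape",
    "write_landscape",
    "generate_synthetic_landscape",
]

NODATA = -9999.0
DEFAULT_INITIAL_LITTER_CM = 13.0
DEFAULT_INITIAL_ACTIVE_LAYER_CM = 60.0


@dataclass
class Landscape:
    """Coarse raster stack plus fine sub-grid state.

    All coarse arrays are (n, n); fine arrays are (n*k, n*k) where
    k = coarse_res_m / fine_res_m.  ``ground_seeds`` maps species name to an
    int32 fine-grid count array (created lazily via :meth:`seed_grid`).
    """

    elevation: np.ndarray
    slope: np.ndarray
    twi: np.ndarray
    water_mask: np.ndarray
    coarse_res_m: float = 90.0
    fine_res_m: float = 0.2
    litter_height: np.ndarray | None = None
    active_layer_depth: np.ndarray | None = None
    last_fire_intensity: np.ndarray | None = None
    ground_seeds: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = self.elevation.shape
        for name in ("slope", "twi", "water_mask"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != {shape}")
        ratio = self.coarse_res_m / self.fine_res_m
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("coarse_res_m must be an integer multiple of fine_res_m")
        self.water_mask = self.water_mask.astype(bool)
        n_fine = self.n_coarse * self.fine_per_coarse
        if self.litter_height is None:
            self.litter_height = np.where(
                self.water_fine, 0.0, DEFAULT_INITIAL_LITTER_CM).astype(np.float32)
        if self.active_layer_depth is None:
            self.active_layer_depth = np.where(
                self.water_fine, 0.0, DEFAULT_INITIAL_ACTIVE_LAYER_CM).astype(np.float32)
        if self.last_fire_intensity is None:
            self.last_fire_intensity = np.zeros((n_fine, n_fine), dtype=np.float32)
        for arr in (self.litter_height, self.active_layer_depth, self.last_fire_intensity):
            if arr.shape != (n_fine, n_fine):
                raise ValueError("fine-grid array shape does not tile the coarse grid")

    # ---- geometry -------------------------------------------------------

    @property
    def n_coarse(self) -> int:
        return self.elevation.shape[0]

    @property
    def fine_per_coarse(self) -> int:
        return int(round(self.coarse_res_m / self.fine_res_m))

    @property
    def n_fine(self) -> int:
        return self.n_coarse * self.fine_per_coarse

    @property
    def width_m(self) -> float:
        return self.n_coarse * self.coarse_res_m

    @property
    def height_m(self) -> float:
        return self.width_m

    @property
    def water_fine(self) -> np.ndarray:
        """Water mask expanded to the fine grid."""
        k = self.fine_per_coarse
        return np.repeat(np.repeat(self.water_mask, k, axis=0), k, axis=1)

    @property
    def land_fine(self) -> np.ndarray:
        return ~self.water_fine

    def fine_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Fine-grid (row, col) of continuous coordinates; row = y, col = x."""
        col = np.clip((np.asarray(x) / self.fine_res_m).astype(int), 0, self.n_fine - 1)
        row = np.clip((np.asarray(y) / self.fine_res_m).astype(int), 0, self.n_fine - 1)
        return row, col

    def coarse_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        col = np.clip((np.asarray(x) / self.coarse_res_m).astype(int), 0, self.n_coarse - 1)
        row = np.clip((np.asarray(y) / self.coarse_res_m).astype(int), 0, self.n_coarse - 1)
        return row, col

    def twi_fine(self) -> np.ndarray:
        """Per-fine-cell TWI inherited from the containing coarse cell."""
        k = self.fine_per_coarse
        return np.repeat(np.repeat(self.twi, k, axis=0), k, axis=1)

    def is_water_xy(self, x, y) -> np.ndarray:
        r, c = self.coarse_index(x, y)
        return self.water_mask[r, c]

    def seed_grid(self, species: str) -> np.ndarray:
        if species not in self.ground_seeds:
            self.ground_seeds[species] = np.zeros(
                (self.n_fine, self.n_fine), dtype=np.int32)
        return self.ground_seeds[species]

    def land_twi_range(self) -> tuple[float, float]:
        vals = self.twi[~self.water_mask]
        if vals.size == 0:
            raise ValueError("landscape has no land cells")
        return float(vals.min()), float(vals.max())


# ---- ESRI ASCII grid IO --------------------------------------------------

def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (array row0=south, header dict)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ESRI ASCII header field '{key}'")
    data = np.loadtxt(lines[i:].__iter__())
    data = np.atleast_2d(data)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (nrows, ncols):
        raise ValueError(f"{path}: data shape {data.shape} != header ({nrows},{ncols})")
    return data[::-1].copy(), header  # ASCII grids store the north row first


def write_ascii_grid(array: np.ndarray, path, cellsize: float,
                     xllcorner: float = 0.0, yllcorner: float = 0.0,
                     nodata: float = NODATA) -> None:
    arr = np.asarray(array, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"ncols {arr.shape[1]}\n")
        fh.write(f"nrows {arr.shape[0]}\n")
        fh.write(f"xllcorner {xllcorner}\n")
        fh.write(f"yllcorner {yllcorner}\n")
        fh.write(f"cellsize {cellsize}\n")
        fh.write(f"NODATA_value {nodata}\n")
        np.savetxt(fh, arr[::-1], fmt="%.6f")


_LAYERS = ("elevation", "slope", "twi", "water")


def read_landscape(paths: dict, fine_res_m: float = 0.2,
                   initial_litter_cm: float = DEFAULT_INITIAL_LITTER_CM) -> Landscape:
    """Assemble a Landscape from ESRI ASCII layer files.

    ``paths`` maps layer name (elevation, slope, twi, water) to a file path.
    All rasters must share shape, cellsize, and origin.  NODATA is tolerated
    only on water cells.
    """
    missing = set(_LAYERS) - set(paths)
    if missing:
        raise ValueError(f"missing landscape layers: {sorted(missing)}")
    arrays, headers = {}, {}
    for layer in _LAYERS:
        arrays[layer], headers[layer] = read_ascii_grid(paths[layer])
    ref = headers["elevation"]
    for layer in _LAYERS[1:]:
        h = headers[layer]
        for key in ("ncols", "nrows", "cellsize", "xllcorner", "yllcorner"):
            if h.get(key, 0.0) != ref.get(key, 0.0):
                raise ValueError(f"layer '{layer}' header {key} mismatch with elevation")
    nodata = ref.get("nodata_value", NODATA)
    water = arrays["water"] > 0.5
    for layer in ("elevation", "slope", "twi"):
        bad = np.isclose(arrays[layer], nodata) & ~water
        if bad.any():
            raise ValueError(f"layer '{layer}': NODATA on {int(bad.sum())} non-water cells")
    scape = Landscape(elevation=arrays["elevation"], slope=arrays["slope"],
                      twi=arrays["twi"], water_mask=water,
                      coarse_res_m=float(ref["cellsize"]), fine_res_m=fine_res_m)
    scape.litter_height = np.where(scape.water_fine, 0.0,
                                   initial_litter_cm).astype(np.float32)
    return scape


def write_landscape(scape: Landscape, directory) -> dict:
    """Write the coarse layers to `<dir>/<layer>.asc`; returns the path map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {"elevation": scape.elevation, "slope": scape.slope,
              "twi": scape.twi, "water": scape.water_mask.astype(float)}
    paths = {}
    for layer, arr in arrays.items():
        p = directory / f"{layer}.asc"
        write_ascii_grid(arr, p, cellsize=scape.coarse_res_m)
        paths[layer] = p
    return paths


# ---- synthetic landscape generation ---------------------------------------

def _fractal_dem(n: int, rng: np.random.Generator, beta: float) -> np.ndarray:
    """Spectral-synthesis fractal surface with power spectrum ~ k^-beta."""
    kx = np.fft.fftfreq(n)[:, None]
    ky = np.fft.fftfreq(n)[None, :]
    k = np.sqrt(kx ** 2 + ky ** 2)
    k[0, 0] = 1.0
    amp = k ** (-beta / 2.0)
    amp[0, 0] = 0.0
    phase = rng.uniform(0, 2 * np.pi, size=(n, n))
    spectrum = amp * np.exp(1j * phase)
    dem = np.real(np.fft.ifft2(spectrum))
    return dem


def _flow_accumulation(elev: np.ndarray, res: float) -> np.ndarray:
    """Single-flow-direction (D8 steepest descent) accumulation, in cells."""
    n, m = elev.shape
    order = np.argsort(elev, axis=None)[::-1]  # high to low
    acc = np.ones_like(elev)
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]
    for flat in order:
        r, c = divmod(int(flat), m)
        best, best_drop = None, 0.0
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < n and 0 <= cc < m:
                dist = np.hypot(dr, dc) * res
                drop = (elev[r, c] - elev[rr, cc]) / dist
                if drop > best_drop:
                    best_drop, best = drop, (rr, cc)
        if best is not None:
            acc[best] += acc[r, c]
    return acc


def compute_twi(elevation: np.ndarray, res: float,
                min_tan_slope: float = 1e-3) -> tuple[np.ndarray, np.ndarray]:
    """Slope (degrees) and TWI = ln(specific catchment area / tan slope)."""
    gy, gx = np.gradient(elevation, res)
    tan_slope = np.sqrt(gx ** 2 + gy ** 2)
    slope_deg = np.degrees(np.arctan(tan_slope))
    acc = _flow_accumulation(elevation, res)
    specific_area = acc * res  # contributing area / contour width
    twi = np.log(specific_area / np.maximum(tan_slope, min_tan_slope))
    return slope_deg, twi


def generate_synthetic_landscape(n_coarse: int,
                                 coarse_res_m: float = 90.0,
                                 fine_res_m: float = 0.2,
                                 relief_m: float = 16.6,
                                 base_elevation_m: float = 106.1,
                                 roughness_beta: float = 3.0,
                                 water_fraction: float = 0.05,
                                 twi_range: tuple[float, float] | None = (7.1, 15.5),
                                 initial_litter_cm: float = DEFAULT_INITIAL_LITTER_CM,
                                 seed: int = 0) -> Landscape:
    """Generate a reproducible fractal landscape.

    A spectral fractal DEM is scaled to ``relief_m`` above
    ``base_elevation_m``; slope comes from central differences and TWI from
    a single-flow-direction accumulation.  If ``twi_range`` is given the TWI
    field is linearly rescaled onto that range (the default matches a
    thermokarst lowland site, TWI 7.1 to 15.5).  The lowest-lying
    ``water_fraction`` of cells is flagged as water.
    """
    if n_coarse < 2:
        raise ValueError("n_coarse must be >= 2")
    rng = np.random.default_rng(seed)
    dem = _fractal_dem(n_coarse, rng, roughness_beta)
    span = dem.max() - dem.min()
    if span > 0:
        dem = (dem - dem.min()) / span * relief_m
    dem = dem + base_elevation_m

    slope, twi = compute_twi(dem, coarse_res_m)
    if twi_range is not None:
        lo, hi = twi_range
        tspan = twi.max() - twi.min()
        if tspan > 0:
            twi = lo + (twi - twi.min()) / tspan * (hi - lo)
        else:
            twi = np.full_like(twi, hi)  # flat: uniform, maximal wetness

    n_water = int(round(water_fraction * n_coarse * n_coarse))
    water = np.zeros_like(dem, dtype=bool)
    if n_water > 0:
        idx = np.argsort(dem, axis=None)[:n_water]
        water.flat[idx] = True

    scape = Landscape(elevation=dem, slope=slope, twi=twi, water_mask=water,
                      coarse_res_m=coarse_res_m, fine_res_m=fine_res_m)
    scape.litter_height = np.where(scape.water_fine, 0.0,
                                   initial_litter_cm).astype(np.float32)
    return scape


def desk_scale_landscape(seed: int = 0, water_fraction: float = 0.0,
                         **kwargs) -> Landscape:
    """A 99 x 99 m landscape (11 coarse cells at 9 m; 495^2 fine cells)."""
    return generate_synthetic_landscape(
        n_coarse=11, coarse_res_m=9.0, water_fraction=water_fraction,
        seed=seed, **kwargs)
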