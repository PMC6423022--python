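"""File formats and the synthetic nanostructured-surface generator.

Height maps travel as plain ASCII: a header line ``nx ny dx dy`` (spacing
in nm) followed by ``ny`` rows of ``nx`` whitespace-separated heights in
nm.  Headerless CSV is also accepted when the grid spacing is supplied by
the caller.  Deposits export as XYZ for generic particle viewers, curves
as tab-separated tables with ``#`` comment headers.

The generator emulates an AFM scan of a black-silicon-like spike field:
randomly placed, minimum-separation-thinned truncated-Gaussian spikes with
jittered height/width, imaged through a finite-radius tip (grayscale
dilation), which reproduces the tip-smoothing artefact of real scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .engine import RsaRunResult
from .geometry import HeightField, InvalidSurfaceError

__all__ = [
    "HeightmapFormatError",
    "SyntheticBsiSpec",
    "generate_synthetic_bsi",
    "read_heightmap",
    "write_heightmap",
    "write_xyz",
    "write_metadata",
    "write_table",
    "read_table",
]


class HeightmapFormatError(ValueError):
    """Malformed height-map file; the message names the offending line."""


# ---------------------------------------------------------------------------
# height-map files
# ---------------------------------------------------------------------------


def read_heightmap(path, csv: bool = False, dx: float | None = None,
                   dy: float | None = None) -> HeightField:
    """Read a height map from native ASCII or headerless CSV.

    The native format carries its own grid spacing; CSV does not, so
    ``dx`` and ``dy`` are then required.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    if csv:
        if dx is None or dy is None:
            raise HeightmapFormatError("CSV height maps carry no grid spacing; pass dx and dy")
        rows = [line for line in text if line.strip()]
        data = []
        width = None
        for ln, line in enumerate(rows, start=1):
            vals = [float(v) for v in line.split(",")]
            if width is None:
                width = len(vals)
            elif len(vals) != width:
                raise HeightmapFormatError(
                    f"{path}: row {ln} has {len(vals)} columns, expected {width}")
            data.append(vals)
        return HeightField(dx, dy, np.array(data))

    lines = [line for line in text if line.strip()]
    if not lines:
        raise HeightmapFormatError(f"{path}: empty file")
    head = lines[0].split()
    if len(head) != 4:
        raise HeightmapFormatError(f"{path}: line 1: header must be 'nx ny dx dy'")
    try:
        nx, ny = int(head[0]), int(head[1])
        hdx, hdy = float(head[2]), float(head[3])
    except ValueError as exc:
        raise HeightmapFormatError(f"{path}: line 1: unparsable header: {exc}") from None
    if len(lines) - 1 != ny:
        raise HeightmapFormatError(f"{path}: expected {ny} data rows, found {len(lines) - 1}")
    data = np.empty((ny, nx))
    for j in range(ny):
        vals = lines[1 + j].split()
        if len(vals) != nx:
            raise HeightmapFormatError(
                f"{path}: line {j + 2}: expected {nx} values, found {len(vals)}")
        try:
            data[j] = [float(v) for v in vals]
        except ValueError as exc:
            raise HeightmapFormatError(f"{path}: line {j + 2}: {exc}") from None
    try:
        return HeightField(hdx, hdy, data)
    except InvalidSurfaceError as exc:
        raise HeightmapFormatError(f"{path}: {exc}") from None


def write_heightmap(hf: HeightField, path, csv: bool = False) -> None:
    """Write a height map; values round-trip exactly (``%.17g``)."""
    path = Path(path)
    sep = "," if csv else " "
    with path.open("w") as fh:
        if not csv:
            fh.write(f"{hf.nx} {hf.ny} {hf.dx:.17g} {hf.dy:.17g}\n")
        for row in hf.z:
            fh.write(sep.join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# deposit / table output
# ---------------------------------------------------------------------------


def write_xyz(result: RsaRunResult, path, species: str = "HSA",
              use_centers: bool = True) -> None:
    """Export deposits as XYZ (species tag + coordinates in nm)."""
    coords = result.centers if use_centers else result.anchors
    with Path(path).open("w") as fh:
        fh.write(f"{len(coords)}\n")
        fh.write(f"theta_end={result.theta_end:.6f} seed={result.seed}\n")
        for x, y, z in coords:
            fh.write(f"{species} {x:.6f} {y:.6f} {z:.6f}\n")


def write_metadata(path, **fields) -> None:
    """Flat ``key = value`` sidecar with run provenance."""
    with Path(path).open("w") as fh:
        for key, val in fields.items():
            fh.write(f"{key} = {val}\n")


def write_table(path, columns: dict, comments: dict | None = None) -> None:
    """Tab-separated table with ``#`` comment header recording provenance."""
    cols = {k: np.asarray(v) for k, v in columns.items()}
    length = {len(v) for v in cols.values()}
    if len(length) != 1:
        raise ValueError("all columns must have equal length")
    with Path(path).open("w") as fh:
        for key, val in (comments or {}).items():
            fh.write(f"# {key} = {val}\n")
        fh.write("# " + "\t".join(cols) + "\n")
        for row in zip(*cols.values()):
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def read_table(path) -> dict:
    """Read back a :func:`write_table` file as ``{column: array}``."""
    lines = Path(path).read_text().splitlines()
    header = None
    rows = []
    for line in lines:
        if line.startswith("#"):
            if "=" not in line:
                header = line[1:].split()
        elif line.strip():
            rows.append([float(v) for v in line.split("\t")])
    data = np.array(rows)
    if header is None or data.ndim != 2 or data.shape[1] != len(header):
        raise ValueError(f"{path}: not a table written by write_table")
    return {name: data[:, i] for i, name in enumerate(header)}


# ---------------------------------------------------------------------------
# synthetic black-silicon-like height field
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticBsiSpec:
    """Parameters of the synthetic spike-field generator.

    Defaults mimic the nominal black-silicon spike dimensions (500 nm tall,
    60 nm wide at half height, ~10% jitter) at a spike density matching the
    periodic-array spacing that gives the reported curved-to-flat area
    ratio (~180 nm spacing, hence ~30 spikes per square micron after
    thinning), imaged on a 512-point-per-2.5-um AFM-like grid through a
    10 nm tip.
    """

    extent: float = 2500.0          # nm, square tile edge
    density: float = 35.0           # candidate spikes per um^2 before thinning
    height_mean: float = 500.0      # nm
    height_sd: float = 50.0
    width_mean: float = 60.0        # nm, width at half height
    width_sd: float = 6.0
    min_separation: float = 80.0    # nm between accepted spike centres
    tip_radius: float = 10.0        # nm, AFM tip sphere
    grid_step: float = 2500.0 / 512.0  # nm per pixel
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("extent", "height_mean", "width_mean", "grid_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.density < 0 or self.height_sd < 0 or self.width_sd < 0:
            raise ValueError("density and jitter scales must be non-negative")
        if self.tip_radius < 0 or self.min_separation < 0:
            raise ValueError("tip radius and separation must be non-negative")


def generate_synthetic_bsi(spec: SyntheticBsiSpec) -> HeightField:
    """Generate a periodic AFM-like spike field; deterministic given the seed.

    Spike centres follow a Poisson process thinned to the minimum
    separation; each keeps its own jittered height and width.  Overlapping
    truncated-Gaussian solids combine by the pointwise maximum, and the
    finite tip radius is applied as a grayscale dilation with a spherical
    structuring element (the standard AFM tip-convolution model).
    """
    rng = np.random.default_rng(spec.seed)
    area_um2 = (spec.extent / 1000.0) ** 2
    # feasibility: thinning cannot sustain densities near disk-packing of
    # the exclusion radius
    if spec.min_separation > 0:
        max_density = 0.5 / (math.pi * (spec.min_separation / 2000.0) ** 2)
        if spec.density > max_density:
            raise ValueError(
                f"density {spec.density}/um^2 is infeasible at min separation "
                f"{spec.min_separation} nm (max ~{max_density:.0f}/um^2)")
    n_cand = rng.poisson(spec.density * area_um2)
    xs = rng.random(n_cand) * spec.extent
    ys = rng.random(n_cand) * spec.extent
    kept_x, kept_y = [], []
    for x, y in zip(xs, ys):
        ok = True
        for kx, ky in zip(kept_x, kept_y):
            ddx = abs(x - kx)
            ddx = min(ddx, spec.extent - ddx)
            ddy = abs(y - ky)
            ddy = min(ddy, spec.extent - ddy)
            if ddx * ddx + ddy * ddy < spec.min_separation ** 2:
                ok = False
                break
        if ok:
            kept_x.append(x)
            kept_y.append(y)

    npix = max(8, int(round(spec.extent / spec.grid_step)))
    step = spec.extent / npix
    ax = (np.arange(npix) + 0.5) * step
    z = np.zeros((npix, npix))
    ln2 = math.log(2.0)
    for x, y in zip(kept_x, kept_y):
        H = rng.normal(spec.height_mean, spec.height_sd)
        W = abs(rng.normal(spec.width_mean, spec.width_sd))
        v = (W / 2.0) ** 2 / (2.0 * ln2)
        r_cut = 3.72 * math.sqrt(v)  # profile decayed to ~1e-3 H
        ddx = np.abs(ax - x)
        ddx = np.minimum(ddx, spec.extent - ddx)
        ddy = np.abs(ax - y)
        ddy = np.minimum(ddy, spec.extent - ddy)
        r2 = ddx[None, :] ** 2 + ddy[:, None] ** 2
        prof = np.where(r2 <= r_cut * r_cut, H * np.exp(-0.5 * r2 / v), 0.0)
        np.maximum(z, prof, out=z)

    if spec.tip_radius > 0:
        z = _tip_dilate(z, spec.tip_radius, step)
    return HeightField(step, step, z)


def _tip_dilate(z: np.ndarray, tip_radius: float, step: float) -> np.ndarray:
    """Grayscale dilation by a spherical tip: the image a blunt tip records."""
    from scipy.ndimage import grey_dilation

    rpix = int(math.ceil(tip_radius / step))
    if rpix < 1:
        return z
    ax = np.arange(-rpix, rpix + 1) * step
    r2 = ax[None, :] ** 2 + ax[:, None] ** 2
    inside = r2 <= tip_radius ** 2
    # structuring element: sphere apex at 0, dropping off toward the rim
    sphere = np.where(inside, np.sqrt(np.maximum(tip_radius ** 2 - r2, 0.0)) - tip_radius,
                      -np.inf)
    return grey_dilation(z, structure=sphere, mode="wrap")
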