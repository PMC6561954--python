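"""Rectilinear volumetric scalar fields and Gaussian-cube I/O.

Everything downstream — near-field weighting, local integration, tip scans —
operates on :class:`VolumetricField` objects: complex scalar values sampled at
the centers of the voxels of an axis-aligned rectilinear grid.  All lengths are
in Ångström internally; the Bohr convention of the cube format is converted at
the I/O boundary and nowhere else.

Quadrature is the midpoint (Riemann) sum with uniform voxel weight,
``sum(values) * voxel_volume``.  This keeps :func:`integrate` exactly linear in
the field values, which the whole intensity pipeline relies on.  Higher-order
quadrature only appears in tests as an independent oracle.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

__all__ = [
    "BOHR_TO_ANGSTROM",
    "COMPONENTS",
    "GridSpec",
    "VolumetricField",
    "CubeFormatError",
    "read_cube",
    "read_complex_cube",
    "write_cube",
    "integrate",
    "pointwise_scale",
    "grids_compatible",
]

#: CODATA Bohr radius in Å, used for the cube-format unit convention.
BOHR_TO_ANGSTROM = 0.52917721092

#: The nine Cartesian polarizability tensor components.
COMPONENTS = frozenset(
    a + b for a in "xyz" for b in "xyz"
)

#: Grid-equality tolerance in Å.
GRID_TOL = 1e-8


class CubeFormatError(ValueError):
    """Raised when a Gaussian cube file cannot be parsed."""


@dataclasses.dataclass
class GridSpec:
    """An axis-aligned rectilinear grid of voxel centers.

    Parameters
    ----------
    origin : (3,) array_like
        Position of the first voxel center, Å.
    step : (3,) array_like
        Per-axis spacing, Å; strictly positive.
    counts : (3,) array_like of int
        Number of voxels per axis; at least 2 per axis.
    """

    origin: np.ndarray
    step: np.ndarray
    counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.step = np.asarray(self.step, dtype=float).reshape(3)
        self.counts = tuple(int(n) for n in np.asarray(self.counts).reshape(3))
        if not np.all(self.step > 0):
            raise ValueError(f"grid steps must be strictly positive, got {self.step}")
        if any(n < 2 for n in self.counts):
            raise ValueError(f"grid needs at least 2 voxels per axis, got {self.counts}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, Å³."""
        return float(np.prod(self.step))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along ``axis`` (0=x, 1=y, 2=z), Å."""
        n = self.counts[axis]
        return self.origin[axis] + self.step[axis] * np.arange(n)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (X, Y, Z) coordinate arrays of voxel centers."""
        return np.meshgrid(
            self.axis_coords(0), self.axis_coords(1), self.axis_coords(2),
            indexing="ij", sparse=True,
        )

    def points(self) -> np.ndarray:
        """All voxel centers as an (nx, ny, nz, 3) array, Å."""
        x, y, z = np.meshgrid(
            self.axis_coords(0), self.axis_coords(1), self.axis_coords(2),
            indexing="ij",
        )
        return np.stack([x, y, z], axis=-1)


@dataclasses.dataclass
class VolumetricField:
    """Complex scalar field sampled on a :class:`GridSpec`.

    ``component`` labels the polarizability tensor element the field belongs
    to (default ``"zz"``, the tip-axis channel).  ``meta`` carries free-form
    provenance: mode id, frequency, displacement sign, source files, and the
    atom block of the originating cube file.
    """

    grid: GridSpec
    values: np.ndarray
    component: str = "zz"
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid counts {self.grid.shape}"
            )
        if self.component not in COMPONENTS:
            raise ValueError(
                f"component {self.component!r} is not a Cartesian tensor pair"
            )

    def copy_with(self, values: np.ndarray, **meta) -> "VolumetricField":
        """New field on the same grid with replaced values and updated meta."""
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return VolumetricField(self.grid, values, self.component, new_meta)


# ---------------------------------------------------------------------------
# Gaussian cube I/O
#
# Header layout: two comment lines; then "natoms ox oy oz"; then three axis
# lines "n vx vy vz"; then natoms atom lines "Z charge x y z"; then the scalar
# block in x-slowest / z-fastest order.  Sign of the voxel counts encodes the
# length unit (positive: Bohr, negative: Å).  natoms < 0 flags an orbital cube
# with a DSET_IDS line, which carries several fields per voxel — unsupported.
# ---------------------------------------------------------------------------


def _parse_header_line(line: str, lineno: int, path: Path) -> list[float]:
    try:
        return [float(tok) for tok in line.split()]
    except ValueError as exc:
        raise CubeFormatError(
            f"{path}: cannot parse header line {lineno}: {line.rstrip()!r}"
        ) from exc


def read_cube(path, part: str = "real") -> VolumetricField:
    """Read a Gaussian cube file into one complex part of a field.

    Parameters
    ----------
    path : path-like
        Cube file with one scalar value per voxel.
    part : {"real", "imaginary"}
        Which complex part the file's values populate; the other part is zero.

    Returns
    -------
    VolumetricField
        Grid in Å regardless of the cube's native unit.  ``meta`` holds the
        two comment lines, the atom block (in Å) and the source path.
    """
    if part not in ("real", "imaginary"):
        raise ValueError(f"part must be 'real' or 'imaginary', got {part!r}")
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 6:
        raise CubeFormatError(f"{path}: truncated header (fewer than 6 lines)")

    comments = [lines[0].rstrip("\n"), lines[1].rstrip("\n")]
    head = _parse_header_line(lines[2], 3, path)
    if len(head) < 4:
        raise CubeFormatError(f"{path}: header line 3 needs natoms + origin, got {lines[2]!r}")
    natoms = int(head[0])
    if natoms < 0:
        raise CubeFormatError(
            f"{path}: natoms < 0 marks a multi-orbital cube layout, which is unsupported"
        )
    if len(head) >= 5 and int(head[4]) != 1:
        raise CubeFormatError(f"{path}: NVal != 1 (multi-valued voxels) is unsupported")
    origin = np.array(head[1:4], dtype=float)

    counts = np.empty(3, dtype=int)
    axes = np.empty((3, 3), dtype=float)
    for i in range(3):
        row = _parse_header_line(lines[3 + i], 4 + i, path)
        if len(row) != 4:
            raise CubeFormatError(f"{path}: axis line {4 + i} must have 4 fields")
        counts[i] = int(row[0])
        axes[i] = row[1:]
    if np.any(counts == 0):
        raise CubeFormatError(f"{path}: zero voxel count on some axis")

    # Unit convention: positive counts => Bohr, negative => Å.
    unit = BOHR_TO_ANGSTROM if np.all(counts > 0) else 1.0
    if not (np.all(counts > 0) or np.all(counts < 0)):
        raise CubeFormatError(f"{path}: mixed count signs {counts.tolist()} are ambiguous")
    counts = np.abs(counts)

    # Only axis-aligned (diagonal axis matrix) grids are supported.
    off_diag = axes - np.diag(np.diag(axes))
    if np.any(np.abs(off_diag) > 1e-12):
        raise CubeFormatError(f"{path}: non-axis-aligned grid axes are unsupported")
    step = np.diag(axes) * unit
    origin = origin * unit

    atoms = []
    for j in range(natoms):
        row = _parse_header_line(lines[6 + j], 7 + j, path)
        if len(row) != 5:
            raise CubeFormatError(f"{path}: atom line {7 + j} must have 5 fields")
        atoms.append((int(row[0]), row[1], tuple(np.array(row[2:]) * unit)))

    flat = np.array(" ".join(lines[6 + natoms:]).split(), dtype=float)
    nvox = int(np.prod(counts))
    if flat.size != nvox:
        raise CubeFormatError(
            f"{path}: expected {nvox} voxel values, found {flat.size}"
        )
    values = flat.reshape(tuple(counts))  # x slowest, z fastest == C order
    if part == "imaginary":
        values = 1j * values

    grid = GridSpec(origin, step, tuple(counts))
    return VolumetricField(
        grid, values, meta={
            "comments": comments, "atoms": atoms, "source": str(path), "part": part,
        },
    )


def read_complex_cube(re_path, im_path=None) -> VolumetricField:
    """Assemble a complex field from a real-part cube and an optional
    imaginary-part cube (the on-disk representation of complex densities).

    The two cubes must be on identical grids.
    """
    field = read_cube(re_path, part="real")
    if im_path is not None:
        im = read_cube(im_path, part="imaginary")
        if not grids_compatible(field.grid, im.grid):
            raise ValueError(
                f"real/imaginary cube grids differ: {re_path} vs {im_path}"
            )
        field = field.copy_with(field.values + im.values,
                                source_im=str(im_path))
    return field


def write_cube(field: VolumetricField, path, part: str = "real") -> None:
    """Write one complex part of a field as a Gaussian cube file.

    The file uses the Å convention (negative voxel counts) so that values
    written round-trip through :func:`read_cube` without unit conversion.
    The atom block from ``field.meta['atoms']`` is preserved when present.
    """
    if part not in ("real", "imaginary"):
        raise ValueError(f"part must be 'real' or 'imaginary', got {part!r}")
    path = Path(path)
    grid = field.grid
    atoms = field.meta.get("atoms", [])
    comments = field.meta.get(
        "comments", ["tersim volumetric field", f"component={field.component} part={part}"]
    )
    data = field.values.real if part == "real" else field.values.imag

    with open(path, "w") as fh:
        fh.write(f"{comments[0]}\n{comments[1] if len(comments) > 1 else ''}\n")
        ox, oy, oz = grid.origin
        fh.write(f"{len(atoms):5d} {ox:15.8f} {oy:15.8f} {oz:15.8f}\n")
        for i in range(3):
            vec = [0.0, 0.0, 0.0]
            vec[i] = grid.step[i]
            fh.write(
                f"{-grid.counts[i]:5d} {vec[0]:15.8f} {vec[1]:15.8f} {vec[2]:15.8f}\n"
            )
        for z, charge, (ax, ay, az) in atoms:
            fh.write(f"{z:5d} {charge:11.6f} {ax:15.8f} {ay:15.8f} {az:15.8f}\n")
        flat = data.ravel(order="C")  # x slowest, z fastest
        for start in range(0, flat.size, 6):
            chunk = flat[start:start + 6]
            fh.write(" ".join(f"{v: .6E}" for v in chunk) + "\n")


# ---------------------------------------------------------------------------
# Field algebra
# ---------------------------------------------------------------------------


def integrate(field: VolumetricField) -> complex:
    """Spatial integral of the field over its grid (midpoint rule), Å³-weighted.

    Returns ``sum(values) * voxel_volume``; exactly linear in the values.
    """
    return complex(field.values.sum() * field.grid.voxel_volume)


def pointwise_scale(field: VolumetricField, weights: np.ndarray) -> VolumetricField:
    """Multiply a field voxelwise by real weights defined on the same grid.

    ``weights`` may be a bare array with the grid's shape or a real
    :class:`VolumetricField` on a compatible grid.  Grid mismatch is a hard
    error — fields are never silently resampled, because the upstream finite
    differencing is only meaningful on identical grids.
    """
    if isinstance(weights, VolumetricField):
        if not grids_compatible(field.grid, weights.grid):
            raise ValueError("weight grid does not match field grid")
        w = weights.values.real
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != field.grid.shape:
            raise ValueError(
                f"weights shape {w.shape} does not match grid counts {field.grid.shape}"
            )
    return field.copy_with(field.values * w)


def grids_compatible(a: GridSpec, b: GridSpec, tol: float = GRID_TOL) -> bool:
    """True iff origin, steps and counts agree within ``tol`` Å."""
    return (
        a.counts == b.counts
        and np.all(np.abs(a.origin - b.origin) <= tol)
        and np.all(np.abs(a.step - b.step) <= tol)
    )
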