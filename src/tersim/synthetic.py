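"""Analytic Raman-polarizability-density fixtures.

Real Raman polarizability densities come from quantum-chemistry response
calculations; what the imaging mechanism actually depends on is only their
sign topology and atom-localization.  This module generates analytic densities
with exactly that structure, so the whole pipeline can be exercised and tested
without any electronic-structure software:

* lobes localized on the atoms (Gaussian envelopes),
* opposite signs above and below the molecular plane for out-of-plane modes
  (an odd factor in z − z_i),
* in-plane sign alternation for anti-symmetric modes (per-atom signs ±1
  alternating around a ring, opposite for para pairs),
* an optional weak imaginary part concentrated below the molecular plane,
  emulating the substrate-induced asymmetry of resonant densities.

The lobe model is a Gaussian times an odd polynomial — no attempt at real
electron structure.  For an out-of-plane mode,

    δρ(r) = Σ_i c_i d_i · (z − z_i)/σ_z
            · exp(−[(x−x_i)² + (y−y_i)²]/(2σ_xy²) − (z−z_i)²/(2σ_z²)),

so δρ is odd in z − z_i by construction and its integral over a symmetric box
vanishes — these are exactly the far-field-silent fixtures that a confined
field re-activates.  In-plane modes replace the odd z factor with an odd
in-plane factor along the displacement direction.

Default grids mirror the reference conventions: 3 Å box margin, 0.4 Å lateral
step, 0.1 Å vertical step.  Default lobe widths are σ_xy = 0.5 Å and
σ_z = 0.4 Å, chosen (arbitrarily) so lobes are resolved on those steps.
Fixtures are deterministic; nothing here draws random numbers.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .raman import NormalMode, RamanDensity, write_mode_table
from .volumetric import GridSpec, VolumetricField, write_cube

__all__ = [
    "ToyMolecule",
    "build_ring",
    "analytic_density",
    "default_grid",
    "rasterize",
    "paired_displacement_cubes",
    "write_bundle",
    "write_xyz",
    "DEFAULT_FREQUENCIES",
]

MODE_KINDS = ("symmetric_oop", "antisymmetric_oop", "inplane")

#: Default mode wavenumbers (cm⁻¹) per fixture kind: the two benzene
#: out-of-plane bending modes, and a generic in-plane value.
DEFAULT_FREQUENCIES = {
    "symmetric_oop": 664.0,
    "antisymmetric_oop": 835.0,
    "inplane": 1178.0,
}


@dataclasses.dataclass
class ToyMolecule:
    """A planar arrangement of atom-centered density lobes.

    Parameters
    ----------
    positions : (n, 3) ndarray
        Atom positions, Å; the molecular plane is z = 0 by convention.
    amplitudes : (n,) complex ndarray
        Per-atom lobe amplitudes c_i.
    signs : (n,) ndarray
        Per-atom displacement signs d_i (±1 patterns).
    kind : {"symmetric_oop", "antisymmetric_oop", "inplane"}
    tangents : (n, 3) ndarray or None
        Unit in-plane displacement directions (in-plane modes only).
    sigma_xy, sigma_z : float
        Lobe widths, Å.
    imag_scale : float
        Relative strength of the below-plane imaginary part (0 = real
        density; 0.2 is a representative weak-resonant setting).
    imag_offset : float or None
        How far below each atom the imaginary lobe is centered, Å
        (default σ_z).
    frequency : float
        Mode wavenumber ν̃_k, cm⁻¹.
    """

    positions: np.ndarray
    amplitudes: np.ndarray
    signs: np.ndarray
    kind: str
    tangents: np.ndarray | None = None
    sigma_xy: float = 0.5
    sigma_z: float = 0.4
    imag_scale: float = 0.0
    imag_offset: float | None = None
    frequency: float | None = None
    index: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.positions)
        self.amplitudes = np.asarray(self.amplitudes, dtype=complex).reshape(n)
        self.signs = np.asarray(self.signs, dtype=float).reshape(n)
        if self.kind not in MODE_KINDS:
            raise ValueError(f"unknown mode kind {self.kind!r}")
        if self.kind == "inplane":
            if self.tangents is None:
                raise ValueError("in-plane modes need tangent directions")
            self.tangents = np.asarray(self.tangents, dtype=float).reshape(n, 3)
        if self.sigma_xy <= 0 or self.sigma_z <= 0:
            raise ValueError("lobe widths must be positive")
        if not np.any(self.amplitudes):
            raise ValueError("at least one lobe amplitude must be non-zero")
        if self.imag_offset is None:
            self.imag_offset = self.sigma_z
        if self.frequency is None:
            self.frequency = DEFAULT_FREQUENCIES[self.kind]
        if not self.label:
            self.label = self.kind

    @property
    def mode(self) -> NormalMode:
        """The normal mode this density derives from (per-atom displacements)."""
        if self.kind == "inplane":
            disp = self.signs[:, None] * self.tangents
        else:
            disp = np.column_stack(
                [np.zeros_like(self.signs), np.zeros_like(self.signs), self.signs]
            )
        return NormalMode(
            index=self.index, frequency=self.frequency,
            displacement=disp, label=self.label,
        )


def build_ring(n_atoms: int, radius: float, mode: str, **kwargs) -> ToyMolecule:
    """A ring of n equally spaced atoms at z = 0 with a mode's sign pattern.

    * ``symmetric_oop`` — all atoms displace out of plane together (d_i = +1).
    * ``antisymmetric_oop`` — signs alternate ±1 around the ring, so para
      pairs (i, i + n/2) displace oppositely; requires even n.
    * ``inplane`` — tangential displacement pattern with alternating signs.
    """
    if n_atoms < 2:
        raise ValueError("a ring needs at least 2 atoms")
    if mode not in MODE_KINDS:
        raise ValueError(f"unknown mode kind {mode!r}")
    if mode == "antisymmetric_oop" and n_atoms % 2:
        raise ValueError("anti-symmetric pattern needs an even atom count")
    theta = 2.0 * np.pi * np.arange(n_atoms) / n_atoms
    positions = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.zeros(n_atoms)]
    )
    if mode == "symmetric_oop":
        signs = np.ones(n_atoms)
    else:
        signs = (-1.0) ** np.arange(n_atoms)
    tangents = None
    if mode == "inplane":
        tangents = np.column_stack([-np.sin(theta), np.cos(theta), np.zeros(n_atoms)])
    amplitudes = kwargs.pop("amplitudes", np.ones(n_atoms))
    return ToyMolecule(
        positions=positions, amplitudes=amplitudes, signs=signs,
        kind=mode, tangents=tangents, **kwargs,
    )


def analytic_density(mol: ToyMolecule, points: np.ndarray) -> np.ndarray:
    """δρ at arbitrary points ((..., 3) Å) — the closed form, vectorized."""
    pts = np.asarray(points, dtype=float)
    scalar = pts.ndim == 1
    pts = pts.reshape(-1, 3)
    out = np.zeros(len(pts), dtype=complex)
    sxy2 = 2.0 * mol.sigma_xy**2
    sz2 = 2.0 * mol.sigma_z**2
    for i, (pos, c, d) in enumerate(zip(mol.positions, mol.amplitudes, mol.signs)):
        delta = pts - pos
        r2_xy = delta[:, 0] ** 2 + delta[:, 1] ** 2
        envelope = np.exp(-r2_xy / sxy2 - delta[:, 2] ** 2 / sz2)
        if mol.kind == "inplane":
            odd = (delta @ mol.tangents[i]) / mol.sigma_xy
        else:
            odd = delta[:, 2] / mol.sigma_z
        out += c * d * odd * envelope
        if mol.imag_scale:
            dz_im = pts[:, 2] - (pos[2] - mol.imag_offset)
            im_env = np.exp(-r2_xy / sxy2 - dz_im**2 / sz2)
            out += 1j * mol.imag_scale * c.real * d * im_env
    return out[0] if scalar else out.reshape(np.asarray(points).shape[:-1])


def default_grid(
    mol: ToyMolecule,
    margin: float = 3.0,
    lateral_step: float = 0.4,
    vertical_step: float = 0.1,
) -> GridSpec:
    """Grid with a 3 Å box margin, symmetric about each axis midpoint.

    Voxel counts are even and centers sit at ±(k + 1/2)·step around the
    molecular center, so a density that is odd about a molecular symmetry
    plane sums to exactly zero (no voxel straddles the node).
    """
    lo = mol.positions.min(axis=0)
    hi = mol.positions.max(axis=0)
    mid = (lo + hi) / 2.0
    half = (hi - lo) / 2.0 + margin
    steps = np.array([lateral_step, lateral_step, vertical_step])
    counts = 2 * np.maximum(np.ceil(half / steps), 1).astype(int)
    origin = mid - (counts / 2.0 - 0.5) * steps
    return GridSpec(origin, steps, tuple(counts))


def rasterize(mol: ToyMolecule, grid: GridSpec | None = None) -> RamanDensity:
    """Sample the analytic density at voxel centers of ``grid``.

    With ``grid=None`` the default grid conventions are used.  The returned
    density carries the molecule's normal mode and an atom block (hydrogens)
    for cube export.
    """
    if grid is None:
        grid = default_grid(mol)
    values = analytic_density(mol, grid.points())
    atoms = [(1, 1.0, tuple(p)) for p in mol.positions]
    field = VolumetricField(
        grid, values,
        meta={
            "atoms": atoms,
            "comments": [f"tersim synthetic density: {mol.label}",
                         f"kind={mol.kind} freq={mol.frequency} cm-1"],
            "mode_index": mol.index,
            "frequency_cm1": mol.frequency,
        },
    )
    return RamanDensity(field=field, mode=mol.mode, dq=None)


def paired_displacement_cubes(
    mol: ToyMolecule, dq: float, directory, grid: GridSpec | None = None
) -> dict:
    """Write displaced-geometry cube pairs with ρ±(r) = ±ΔQ·δρ(r).

    The density is exactly linear in Q, so the central difference of the pair
    recovers δρ exactly, independent of ΔQ.  Files follow the ingestion
    convention ``<label>_<plus|minus>_<re|im>.cube``; imaginary-part cubes are
    written only for complex fixtures.

    Returns a dict of the written paths keyed by (sign, part).
    """
    if dq <= 0:
        raise ValueError(f"dq must be positive, got {dq}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rd = rasterize(mol, grid)
    label = mol.label
    is_complex = bool(np.any(rd.field.values.imag))
    paths = {}
    for sign, factor in (("plus", dq), ("minus", -dq)):
        displaced = rd.field.copy_with(factor * rd.field.values, sign=sign)
        parts = ["real", "imaginary"] if is_complex else ["real"]
        for part in parts:
            suffix = "re" if part == "real" else "im"
            path = directory / f"{label}_{sign}_{suffix}.cube"
            write_cube(displaced, path, part=part)
            paths[(sign, suffix)] = path
    return paths


def write_xyz(positions: np.ndarray, path, element: str = "H", comment: str = "") -> None:
    """Write atom positions as a plain XYZ file."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    with open(path, "w") as fh:
        fh.write(f"{len(positions)}\n{comment}\n")
        for x, y, z in positions:
            fh.write(f"{element} {x:15.8f} {y:15.8f} {z:15.8f}\n")


def write_bundle(
    mols: list[ToyMolecule], dq: float, directory, grid: GridSpec | None = None
) -> dict:
    """Write a complete fixture bundle: cube pairs, XYZ geometry, mode table.

    All molecules must share atom positions (they are modes of one geometry);
    a common grid is built from the first molecule when none is given.  The
    bundle is immediately consumable by the imaging pipeline and the CLI.
    """
    if not mols:
        raise ValueError("write_bundle needs at least one molecule")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if grid is None:
        grid = default_grid(mols[0])
    seen = set()
    paths = {"cubes": {}}
    for mol in mols:
        if mol.label in seen:
            raise ValueError(f"duplicate mode label {mol.label!r} in bundle")
        seen.add(mol.label)
        paths["cubes"][mol.label] = paired_displacement_cubes(mol, dq, directory, grid)
    xyz_path = directory / "geometry.xyz"
    write_xyz(mols[0].positions, xyz_path, comment="tersim synthetic fixture")
    modes_path = directory / "modes.txt"
    write_mode_table([m.mode for m in mols], modes_path)
    manifest = {
        "dq": dq,
        "modes": {
            m.label: {"index": m.index, "frequency_cm1": m.frequency}
            for m in mols
        },
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["xyz"] = xyz_path
    paths["modes"] = modes_path
    paths["manifest"] = directory / "manifest.json"
    paths["dq"] = dq
    return paths
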