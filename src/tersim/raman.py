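"""Raman polarizability densities from densities at displaced geometries.

The Raman polarizability density of mode k is the derivative of the
polarizability density along the normal coordinate, δρ = ∂ρ/∂Q_k, obtained
here by the central (three-point) finite-difference stencil from densities at
geometries displaced by ±ΔQ along the mode.  For resonant excitation the
densities, and hence δρ, are complex; the real and imaginary parts are stored
on disk as paired cubes with the ``_re`` / ``_im`` suffix convention
``<mode>_<plus|minus>_<re|im>.cube``.

Display normalization (:func:`normalize_for_display`) is deliberately
quarantined from the physics path: intensities are computed from unnormalized
densities only, so per-mode rescaling can never leak into image contrast.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .volumetric import (
    VolumetricField,
    grids_compatible,
    read_complex_cube,
)

__all__ = [
    "NormalMode",
    "RamanDensity",
    "central_difference",
    "normalize_for_display",
    "split_parts",
    "read_mode_table",
    "write_mode_table",
    "load_mode_density",
    "discover_modes",
]


@dataclasses.dataclass
class NormalMode:
    """A vibrational normal mode.

    Parameters
    ----------
    index : int
        Mode number k.
    frequency : float
        Harmonic wavenumber ν̃_k, cm⁻¹; must be positive to enter a cross
        section.
    displacement : (n_atoms, 3) ndarray
        Per-atom displacement direction of the normal coordinate
        (dimensionless); must not be all zero.
    label : str
        Free-text tag (e.g. "sym-oop-bend").
    """

    index: int
    frequency: float
    displacement: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 2 or self.displacement.shape[1] != 3:
            raise ValueError("displacement must be an (n_atoms, 3) array")
        if not np.any(self.displacement):
            raise ValueError("displacement vector must be non-zero")


@dataclasses.dataclass
class RamanDensity:
    """δρ = ∂ρ/∂Q_k on a grid, with the mode and the ΔQ used to build it."""

    field: VolumetricField
    mode: NormalMode | None = None
    dq: float | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.field.values.view(float))):
            raise ValueError("Raman density contains non-finite values")


def central_difference(
    rho_plus: VolumetricField,
    rho_minus: VolumetricField,
    dq: float,
    mode: NormalMode | None = None,
) -> RamanDensity:
    """δρ = (ρ(+ΔQ) − ρ(−ΔQ)) / (2 ΔQ), voxelwise and complex.

    The central stencil is exact for densities linear in Q, antisymmetric
    under swapping ρ₊ and ρ₋, and linear in both inputs.  The grids must be
    identical (no resampling).
    """
    if dq <= 0:
        raise ValueError(f"displacement step dq must be positive, got {dq}")
    if not grids_compatible(rho_plus.grid, rho_minus.grid):
        raise ValueError("displaced-geometry densities are on incompatible grids")
    values = (rho_plus.values - rho_minus.values) / (2.0 * dq)
    field = rho_plus.copy_with(
        values,
        dq=dq,
        provenance="central_difference(+dQ, -dQ)",
    )
    return RamanDensity(field=field, mode=mode, dq=dq)


def normalize_for_display(rd: RamanDensity) -> VolumetricField:
    """Field scaled to max |value| = 1, for isosurface plots only.

    The intensity pipeline never consumes this output.
    """
    peak = np.max(np.abs(rd.field.values))
    if peak == 0:
        raise ValueError("cannot display-normalize an all-zero density")
    return rd.field.copy_with(rd.field.values / peak, normalized=True)


def split_parts(rd: RamanDensity) -> tuple[VolumetricField, VolumetricField]:
    """(real part, imaginary part) as two real-valued fields; rd = re + i·im."""
    re = rd.field.copy_with(rd.field.values.real.astype(complex), part="real")
    im = rd.field.copy_with(rd.field.values.imag.astype(complex), part="imaginary")
    return re, im


# ---------------------------------------------------------------------------
# Mode tables and on-disk density bundles
# ---------------------------------------------------------------------------


def read_mode_table(path) -> list[NormalMode]:
    """Read a plain-text mode table.

    Whitespace-delimited columns: mode index, frequency (cm⁻¹), atom index,
    dx, dy, dz.  Lines starting with ``#`` are comments.  Rows of one mode
    must share a frequency; atom indices are 0-based and must tile 0..n-1.
    """
    rows: dict[int, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if len(toks) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(toks)}")
            k, freq, atom = int(toks[0]), float(toks[1]), int(toks[2])
            vec = [float(t) for t in toks[3:6]]
            entry = rows.setdefault(k, {"freq": freq, "atoms": {}})
            if entry["freq"] != freq:
                raise ValueError(f"{path}:{lineno}: inconsistent frequency for mode {k}")
            entry["atoms"][atom] = vec
    modes = []
    for k in sorted(rows):
        atoms = rows[k]["atoms"]
        n = max(atoms) + 1
        if sorted(atoms) != list(range(n)):
            raise ValueError(f"mode {k}: atom indices must cover 0..{n - 1}")
        disp = np.array([atoms[i] for i in range(n)])
        modes.append(NormalMode(index=k, frequency=rows[k]["freq"], displacement=disp))
    return modes


def write_mode_table(modes: list[NormalMode], path) -> None:
    """Write modes in the format read by :func:`read_mode_table`."""
    with open(path, "w") as fh:
        fh.write("# mode  frequency_cm-1  atom  dx  dy  dz\n")
        for m in modes:
            for i, (dx, dy, dz) in enumerate(m.displacement):
                fh.write(
                    f"{m.index:4d} {m.frequency:12.4f} {i:4d}"
                    f" {dx: .8f} {dy: .8f} {dz: .8f}\n"
                )


def discover_modes(directory) -> list[str]:
    """Mode labels present in a density directory.

    A mode ``<label>`` is present when ``<label>_plus_re.cube`` exists.
    """
    directory = Path(directory)
    labels = sorted(
        p.name[: -len("_plus_re.cube")] for p in directory.glob("*_plus_re.cube")
    )
    return labels


def load_mode_density(
    directory, label: str, dq: float, mode: NormalMode | None = None
) -> RamanDensity:
    """Load a mode's displaced-geometry cube pair and finite-difference it.

    Expects ``<label>_plus_re.cube`` and ``<label>_minus_re.cube``; the
    ``_im`` companions are picked up when present (resonant densities).
    """
    directory = Path(directory)

    def _read(sign: str) -> VolumetricField:
        re_path = directory / f"{label}_{sign}_re.cube"
        if not re_path.exists():
            raise FileNotFoundError(f"missing density cube {re_path}")
        im_path = directory / f"{label}_{sign}_im.cube"
        return read_complex_cube(re_path, im_path if im_path.exists() else None)

    return central_difference(_read("plus"), _read("minus"), dq, mode=mode)
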