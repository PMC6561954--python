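"""Confined plasmonic near-field profiles.

The tip-induced near field is modeled as a scalar amplitude profile
``F(r - R)`` of unit peak centered at the tip position ``R``, with per-axis
full widths at half maximum (FWHM).  Two profiles are provided:

* ``lorentzian3d`` — ``F(r) = 1 / (1 + sum_a (2 Δ_a / w_a)^2)``, the minimal
  3D generalization of a Lorentzian with per-axis FWHM ``w_a``; heavier tails
  than the Gaussian, capturing the residual background field away from the tip.
* ``gaussian3d`` — ``F(r) = exp(-4 ln 2 · sum_a (Δ_a / w_a)^2)``.

Both equal 1 at the center and exactly 0.5 at a single-axis offset of half a
FWHM.  The amplitude is pinned to 1 (unit external field): absolute field
enhancement is a constant prefactor that cancels out of image contrast.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .volumetric import GridSpec

__all__ = ["NearField", "PRESETS", "preset"]

_LN2_4 = 4.0 * np.log(2.0)

_PROFILES = ("lorentzian3d", "gaussian3d")


@dataclasses.dataclass
class NearField:
    """A confined near-field distribution F(r - R).

    Parameters
    ----------
    profile : {"lorentzian3d", "gaussian3d"}
    fwhm : (3,) array_like
        Per-axis full widths at half maximum (w_x, w_y, w_z), Å; all > 0.
    center : (3,) array_like
        Field center R, Å.  By convention the molecular plane is at z = 0, so
        a tip height h puts the center at (x_tip, y_tip, h).
    """

    profile: str
    fwhm: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        if self.profile not in _PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}; use one of {_PROFILES}")
        self.fwhm = np.asarray(self.fwhm, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if not np.all(self.fwhm > 0):
            raise ValueError(f"FWHMs must be positive, got {self.fwhm}")

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Field amplitude at the given points, in (0, 1].

        ``points`` is (..., 3) in Å; the result has shape ``points.shape[:-1]``.
        """
        pts = np.asarray(points, dtype=float)
        delta = pts - self.center
        u = delta / self.fwhm
        q = np.sum(u * u, axis=-1)  # sum_a (Δ_a / w_a)^2
        if self.profile == "lorentzian3d":
            return 1.0 / (1.0 + 4.0 * q)
        return np.exp(-_LN2_4 * q)

    def sample_on_grid(self, grid: GridSpec) -> np.ndarray:
        """Field amplitude at every voxel center of ``grid``.

        Uses the separable structure of both profiles: the per-axis quadratic
        terms are computed once per axis and broadcast, so sampling costs
        O(nx + ny + nz) evaluations plus one broadcast sum.
        """
        q = 0.0
        for axis in range(3):
            u = (grid.axis_coords(axis) - self.center[axis]) / self.fwhm[axis]
            shape = [1, 1, 1]
            shape[axis] = -1
            q = q + (u * u).reshape(shape)
        if self.profile == "lorentzian3d":
            return 1.0 / (1.0 + 4.0 * q)
        return np.exp(-_LN2_4 * q)

    def shifted(self, tip_xy_z: np.ndarray) -> "NearField":
        """Copy of this field re-centered at ``tip_xy_z``."""
        return NearField(self.profile, self.fwhm, np.asarray(tip_xy_z, dtype=float))


#: Field parameters used for the reference molecules: per-axis FWHMs (Å) and
#: tip height above the molecular plane (Å).
PRESETS: dict[str, dict] = {
    "benzene": {"fwhm": (1.3, 1.3, 1.3), "height": 1.0},
    "porphyrin": {"fwhm": (2.0, 2.0, 2.0), "height": 1.5},
    "h2tbpp": {"fwhm": (12.0, 12.0, 6.0), "height": 2.7},
    "porphycene": {"fwhm": (5.0, 5.0, 5.0), "height": 2.0},
}


def preset(name: str, profile: str = "lorentzian3d") -> tuple[str, np.ndarray, float]:
    """Return (profile, fwhm, height) for a named reference configuration.

    Heights are measured from the molecular plane (z = 0, the mean plane of
    the heavy atoms) to the field center.
    """
    try:
        p = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; known: {sorted(PRESETS)}"
        ) from None
    return profile, np.asarray(p["fwhm"], dtype=float), float(p["height"])
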