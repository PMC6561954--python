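"""Local integration of Raman polarizability densities and tip scans.

The confined near field selects a sub-molecular piece of the Raman
polarizability density.  With the field entering once for the incident and
once for the scattered photon, the effective density at tip position R is

    δρ_loc(r, R) = F(r − R) · δρ(r) · F(r − R),

its spatial integral is the near-field Raman polarizability α′_k(R), and the
TERS intensity at R is |α′_k(R)|² (squared modulus, so the complex resonant
case is handled uniformly).  A TERS image is this intensity evaluated on a
lateral grid of tip positions at fixed height.  With a uniform field (F ≡ 1)
the integral reduces to the far-field Raman polarizability, which obeys the
conventional selection rules; the confined field breaks the cancellation of
opposite-signed density lobes and activates far-field-silent modes.

The integration domain is always the full density grid: the decay of F
performs the localization, mirroring the fact that integration over all space
is effectively local once the field is confined.  Densities are
tip-independent, so a scan reuses one density under many field samplings.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np

from .nearfield import NearField
from .raman import RamanDensity
from .volumetric import VolumetricField, integrate, pointwise_scale

__all__ = [
    "ScanPlan",
    "TERSImage",
    "effective_density",
    "local_polarizability",
    "intensity",
    "far_field",
    "scan",
]


@dataclasses.dataclass
class ScanPlan:
    """A lateral tip scan at fixed height.

    Parameters
    ----------
    x_range, y_range : (min, max) tuples, Å
        Scan window; inclusive of the endpoints up to step rounding.
    step : float
        Lateral scan step, Å (default 0.2).
    height : float
        Tip height z of the field center, Å above the molecular plane (z = 0).
    profile : str
        Near-field profile for every tip position.
    fwhm : (3,) array_like
        Per-axis FWHMs of the field, Å.
    """

    x_range: tuple[float, float]
    y_range: tuple[float, float]
    height: float
    fwhm: np.ndarray
    profile: str = "lorentzian3d"
    step: float = 0.2

    def __post_init__(self) -> None:
        self.fwhm = np.asarray(self.fwhm, dtype=float).reshape(3)
        if self.step <= 0:
            raise ValueError(f"scan step must be positive, got {self.step}")
        if self.x_range[1] < self.x_range[0] or self.y_range[1] < self.y_range[0]:
            raise ValueError("scan ranges must be non-empty (max >= min)")
        # Validate field parameters early via a throwaway instance.
        NearField(self.profile, self.fwhm, (0.0, 0.0, self.height))

    def _axis_values(self, rng: tuple[float, float]) -> np.ndarray:
        lo, hi = rng
        n = int(np.floor((hi - lo) / self.step + 1e-9)) + 1
        return lo + self.step * np.arange(n)

    @property
    def x_values(self) -> np.ndarray:
        return self._axis_values(self.x_range)

    @property
    def y_values(self) -> np.ndarray:
        return self._axis_values(self.y_range)

    def field_at(self, x: float, y: float) -> NearField:
        return NearField(self.profile, self.fwhm, (x, y, self.height))


@dataclasses.dataclass
class TERSImage:
    """A 2D map of TERS intensities over tip positions.

    ``intensities[i, j]`` is the intensity at tip position
    ``(x[i], y[j], height)``; all entries are non-negative by construction.
    ``meta`` records provenance: mode id(s), field parameters, height, band.
    """

    intensities: np.ndarray
    x: np.ndarray
    y: np.ndarray
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.intensities.shape != (self.x.size, self.y.size):
            raise ValueError(
                f"intensity shape {self.intensities.shape} does not match"
                f" ({self.x.size}, {self.y.size}) tip positions"
            )
        if np.any(self.intensities < 0):
            raise ValueError("TERS intensities must be non-negative")

    @property
    def max(self) -> float:
        return float(self.intensities.max())

    def pixel_nearest(self, x: float, y: float) -> float:
        """Intensity at the tip position nearest (x, y)."""
        i = int(np.argmin(np.abs(self.x - x)))
        j = int(np.argmin(np.abs(self.y - y)))
        return float(self.intensities[i, j])

    def save_text(self, path, sidecar: bool = True) -> None:
        """Write the intensity matrix as delimited text plus a JSON sidecar.

        Rows of the matrix run along x, columns along y, matching
        ``intensities``.  The sidecar ``<path>.json`` stores the axes and the
        provenance metadata.
        """
        path = Path(path)
        np.savetxt(path, self.intensities, fmt="%.12e")
        if sidecar:
            meta = {
                "x": self.x.tolist(),
                "y": self.y.tolist(),
                "layout": "rows: x, cols: y",
                **_jsonable(self.meta),
            }
            with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
                json.dump(meta, fh, indent=2, sort_keys=True)


def _jsonable(meta: dict) -> dict:
    out = {}
    for k, v in meta.items():
        if isinstance(v, np.ndarray):
            out[k] = v.tolist()
        elif isinstance(v, (np.floating, np.integer)):
            out[k] = v.item()
        else:
            out[k] = v
    return out


# ---------------------------------------------------------------------------
# The local integration operator
# ---------------------------------------------------------------------------


def effective_density(rd: RamanDensity, nf: NearField) -> VolumetricField:
    """δρ_loc(r, R) = F(r−R) δρ(r) F(r−R): the density weighted by F²."""
    f = nf.sample_on_grid(rd.field.grid)
    return pointwise_scale(rd.field, f * f)


def local_polarizability(rd: RamanDensity, nf: NearField) -> complex:
    """Near-field Raman polarizability α′_k(R) = ∫ F² δρ dV (complex, Å³)."""
    return integrate(effective_density(rd, nf))


def intensity(rd: RamanDensity, nf: NearField) -> float:
    """TERS intensity |α′_k(R)|² at the field's tip position."""
    return abs(local_polarizability(rd, nf)) ** 2


def far_field(rd: RamanDensity) -> complex:
    """Far-field Raman polarizability: ∫ δρ dV, the uniform-field limit."""
    return integrate(rd.field)


def scan(rd, plan: ScanPlan):
    """Evaluate the TERS intensity at every tip position of a scan plan.

    Parameters
    ----------
    rd : RamanDensity or sequence of RamanDensity
        One density per mode; all must share a grid layout.
    plan : ScanPlan

    Returns
    -------
    TERSImage or list of TERSImage
        One image per mode, in input order; a single density yields a single
        image.

    Notes
    -----
    The density is independent of the tip position, so the scan reuses the
    density array and only resamples F at each tip.  F² is assembled from
    per-axis terms: the z-axis term is constant over the scan and the x/y
    terms depend on a single tip coordinate each, so they are precomputed per
    scan row/column.
    """
    single = isinstance(rd, RamanDensity)
    densities: list[RamanDensity] = [rd] if single else list(rd)
    if not densities:
        raise ValueError("scan needs at least one density")
    grid = densities[0].field.grid
    from .volumetric import grids_compatible

    for other in densities[1:]:
        if not grids_compatible(grid, other.field.grid):
            raise ValueError("densities in one scan must share a grid")

    xs, ys = plan.x_values, plan.y_values
    _warn_if_outside(grid, xs, ys)

    gx = grid.axis_coords(0)
    gy = grid.axis_coords(1)
    gz = grid.axis_coords(2)
    wx, wy, wz = plan.fwhm
    # Per-axis quadratic terms (Δ_a / w_a)²: tips × grid for x and y, fixed for z.
    qx = ((gx[None, :] - xs[:, None]) / wx) ** 2  # (n_tip_x, nx)
    qy = ((gy[None, :] - ys[:, None]) / wy) ** 2  # (n_tip_y, ny)
    qz = ((gz - plan.height) / wz) ** 2           # (nz,)

    vol = grid.voxel_volume
    lorentzian = plan.profile == "lorentzian3d"
    vals = [d.field.values for d in densities]

    if not lorentzian:
        # Gaussian factorizes: F² = e^{-8ln2 qx} e^{-8ln2 qy} e^{-8ln2 qz},
        # so α′(R) is a pair of small matrix contractions per mode.
        c = 8.0 * np.log(2.0)
        ex = np.exp(-c * qx)            # (ntx, nx)
        ey = np.exp(-c * qy)            # (nty, ny)
        ez = np.exp(-c * qz)            # (nz,)
        images = []
        for d, v in zip(densities, vals):
            vz = v @ ez                  # (nx, ny)
            alpha = ex @ vz @ ey.T * vol  # (ntx, nty)
            images.append(_make_image(np.abs(alpha) ** 2, xs, ys, plan, d))
        return images[0] if single else images

    alpha = np.zeros((len(densities), xs.size, ys.size), dtype=complex)
    for i in range(xs.size):
        qxy = qx[i][:, None, None] + qz[None, None, :]  # (nx, 1, nz)
        for j in range(ys.size):
            f = 1.0 / (1.0 + 4.0 * (qxy + qy[j][None, :, None]))
            f *= f
            for m, v in enumerate(vals):
                alpha[m, i, j] = np.sum(v * f)
    alpha *= vol
    images = [
        _make_image(np.abs(alpha[m]) ** 2, xs, ys, plan, d)
        for m, d in enumerate(densities)
    ]
    return images[0] if single else images


def _make_image(
    intens: np.ndarray, xs: np.ndarray, ys: np.ndarray, plan: ScanPlan, d: RamanDensity
) -> TERSImage:
    mode = d.mode
    meta = {
        "mode_index": mode.index if mode else None,
        "frequency_cm1": mode.frequency if mode else None,
        "mode_label": mode.label if mode else None,
        "profile": plan.profile,
        "fwhm": plan.fwhm.tolist(),
        "height": plan.height,
        "scan_step": plan.step,
        "component": d.field.component,
    }
    return TERSImage(intens, xs, ys, meta)


def _warn_if_outside(grid, xs: np.ndarray, ys: np.ndarray) -> None:
    gx = grid.axis_coords(0)
    gy = grid.axis_coords(1)
    if xs.max() < gx.min() or xs.min() > gx.max() or ys.max() < gy.min() or ys.min() > gy.max():
        warnings.warn(
            "scan window lies entirely outside the density grid; the image"
            " will be near zero",
            stacklevel=3,
        )
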