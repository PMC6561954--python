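import math

import numpy as np
import pytest

import tersim as ts


@pytest.fixture(scope="session")
def ring_antisym():
    """Six-lobe ring with alternating out-of-plane signs (far-field silent)."""
    return ts.build_ring(6, 2.5, "antisymmetric_oop")


@pytest.fixture(scope="session")
def ring_sym():
    """Six-lobe ring with all-equal out-of-plane signs."""
    return ts.build_ring(6, 2.5, "symmetric_oop")


@pytest.fixture(scope="session")
def rd_antisym(ring_antisym):
    return ts.rasterize(ring_antisym)


@pytest.fixture(scope="session")
def rd_sym(ring_sym):
    return ts.rasterize(ring_sym)


@pytest.fixture
def blob_density():
    """All-positive Gaussian blob: a density with a non-zero far field."""
    grid = ts.GridSpec((-2.0, -2.0, -2.0), (0.25, 0.25, 0.25), (17, 17, 17))
    x, y, z = grid.meshgrid()
    vals = np.exp(-(x**2 + y**2 + z**2) / 2.0)
    return ts.RamanDensity(ts.VolumetricField(grid, vals))


def brute_force_image(rd, plan):
    """Independent oracle: per-pixel triple loop over voxels in plain Python.

    Evaluates F at each voxel with scalar math, accumulates F^2 * value, and
    squares the modulus — no shared code with the scan engine beyond the grid
    coordinate definition.
    """
    grid = rd.field.grid
    xs = [grid.origin[0] + grid.step[0] * i for i in range(grid.counts[0])]
    ys = [grid.origin[1] + grid.step[1] * j for j in range(grid.counts[1])]
    zs = [grid.origin[2] + grid.step[2] * k for k in range(grid.counts[2])]
    vol = grid.step[0] * grid.step[1] * grid.step[2]
    wx, wy, wz = (float(w) for w in plan.fwhm)
    vals = rd.field.values
    out = np.empty((plan.x_values.size, plan.y_values.size))
    for a, tx in enumerate(plan.x_values):
        for b, ty in enumerate(plan.y_values):
            acc = 0.0 + 0.0j
            for i, gx in enumerate(xs):
                for j, gy in enumerate(ys):
                    for k, gz in enumerate(zs):
                        q = ((gx - tx) / wx) ** 2 + ((gy - ty) / wy) ** 2 \
                            + ((gz - plan.height) / wz) ** 2
                        if plan.profile == "lorentzian3d":
                            f = 1.0 / (1.0 + 4.0 * q)
                        else:
                            f = math.exp(-4.0 * math.log(2.0) * q)
                        acc += f * f * vals[i, j, k]
            out[a, b] = abs(acc * vol) ** 2
    return out


@pytest.fixture
def brute_force():
    return brute_force_image
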