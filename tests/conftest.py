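import numpy as np
import pytest

from porelume import synthgen as sg


@pytest.fixture(scope="session")
def fixture_suite(tmp_path_factory):
    """The canonical synthetic fixture set (written once per session)."""
    out = tmp_path_factory.mktemp("suite")
    manifest = sg.make_fixture_suite(out, seed=7)
    return out, manifest


@pytest.fixture(scope="session")
def ring18():
    """Cylindrical 10-fold ring channel with lumen radius exactly 18 A."""
    return sg.make_ring_channel(
        sg.ChannelSpec(n_subunits=10, lumen_knots=((-20.0, 18.0), (20.0, 18.0)), seed=3)
    )


def brute_force_station_radius(coords, radii, z, bound, grid=0.02):
    """Independent dense-grid oracle for the planar inscribed-sphere radius.

    Evaluates min_i(|p - c_i| - r_i) on a *grid*-spaced lattice over the
    disc of radius *bound* in the plane at height *z* (axis = lattice z
    through the origin) and returns the maximum, clamped at 0.
    """
    ax = np.arange(-bound, bound + grid / 2, grid)
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])
    pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= bound]
    dz2 = (coords[:, 2] - z) ** 2
    best = -np.inf
    for i in range(0, len(pts), 20000):
        chunk = pts[i:i + 20000]
        d = np.sqrt(
            (chunk[:, 0:1] - coords[None, :, 0]) ** 2
            + (chunk[:, 1:2] - coords[None, :, 1]) ** 2
            + dz2[None, :]
        ) - radii[None, :]
        best = max(best, float(d.min(axis=1).max()))
    return max(best, 0.0)


@pytest.fixture(scope="session")
def brute_station_oracle():
    return brute_force_station_radius
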