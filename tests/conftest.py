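"""Shared fixtures: synthetic phantoms and precomputed pipeline states.

Everything is generated at test time from fixed seeds; the heavier states
(default noisy phantom + its centerline + fitted baseline surface) are
session-scoped so that the many tests probing them pay the cost once.
"""

import numpy as np
import pytest
from hypothesis import settings

from aortrack import (
    AortaPhantomSpec,
    GridSpec,
    detect_endpoints,
    extract_path,
    fit_lumen_model,
    generate_baseline,
    recenter,
    segment_baseline,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def networkx_path_cost(vol, model, start, end, length_penalty=0.01):
    """Independent shortest-path oracle: the same voxel-graph optimization
    posed to networkx (for toy grids only)."""
    import networkx as nx

    from aortrack import voxel_cost

    cost = np.asarray(voxel_cost(vol.voxels, model), dtype=float) + length_penalty
    sp = vol.spacing[::-1]
    shape = vol.voxels.shape
    G = nx.Graph()
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                for dz in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            if (dz, dy, dx) == (0, 0, 0):
                                continue
                            v = (z + dz, y + dy, x + dx)
                            if not all(0 <= v[k] < shape[k] for k in range(3)):
                                continue
                            step = float(np.linalg.norm(np.array([dz, dy, dx]) * sp))
                            w = 0.5 * (cost[z, y, x] + cost[v]) * step
                            G.add_edge((z, y, x), v, weight=w)
    s = tuple(np.rint(vol.world_to_voxel(start)).astype(int)[::-1])
    e = tuple(np.rint(vol.world_to_voxel(end)).astype(int)[::-1])
    return nx.shortest_path_length(G, s, e, weight="weight")


def straight_tube_spec(radius=15.0, length=120.0, taper_to=None, **kwargs):
    """A vertical straight-tube phantom spec (clean fixture geometry)."""
    pts = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, length]])
    r_end = radius if taper_to is None else taper_to
    defaults = dict(blur_sigma=0.0, noise_sigma=0.0, texture_sigma=0.0, seed=5)
    defaults.update(kwargs)
    return AortaPhantomSpec(
        curve_points=pts,
        radius_knots=((0.0, radius), (1.0, r_end)),
        **defaults,
    )


@pytest.fixture(scope="session")
def cylinder_phantom():
    """Noiseless blurred cylinder, radius 15 mm: the analytic segmentation
    oracle (distance-to-axis is closed form)."""
    spec = straight_tube_spec(radius=15.0, length=100.0, blur_sigma=0.6)
    grid = GridSpec.fit(spec, spacing=1.0)
    vol, truth = generate_baseline(spec, grid)
    return spec, grid, vol, truth


@pytest.fixture(scope="session")
def default_phantom():
    """Default noisy candy-cane phantom at 1 mm isotropic."""
    spec = AortaPhantomSpec(seed=11)
    grid = GridSpec.fit(spec, spacing=1.0)
    vol, truth = generate_baseline(spec, grid)
    return spec, grid, vol, truth


@pytest.fixture(scope="session")
def baseline_state(default_phantom):
    """Lumen model, extracted centerline and fitted baseline surface for the
    default phantom."""
    spec, grid, vol, truth = default_phantom
    model = fit_lumen_model(vol, truth.landmarks["DESC"]["point"], 5.0)
    root, desc = detect_endpoints(vol, model)
    cl = recenter(extract_path(vol, model, root, desc), vol, model)
    mesh = segment_baseline(vol, cl)
    return {"model": model, "centerline": cl, "mesh": mesh}


@pytest.fixture(scope="session")
def registration_phantom():
    """Default phantom on a grid with extra margin so transformed follow-ups
    stay inside, plus its baseline segmentation state."""
    spec = AortaPhantomSpec(seed=11)
    grid = GridSpec.fit(spec, spacing=1.0, margin=25.0)
    vol, truth = generate_baseline(spec, grid)
    model = fit_lumen_model(vol, truth.landmarks["DESC"]["point"], 5.0)
    root, desc = detect_endpoints(vol, model)
    cl = recenter(extract_path(vol, model, root, desc), vol, model)
    mesh = segment_baseline(vol, cl)
    return {"spec": spec, "grid": grid, "vol": vol, "truth": truth,
            "model": model, "centerline": cl, "mesh": mesh}
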