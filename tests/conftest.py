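"""Shared fixtures: small hand-built connectomes and cached synthetic runs."""

from __future__ import annotations

import numpy as np
import pytest

import usfc
from usfc.io import ConnMatrix, RegionAtlas


@pytest.fixture
def line_atlas() -> RegionAtlas:
    """Four collinear regions 10 mm apart along x."""
    return RegionAtlas(
        region_ids=(1, 2, 3, 4),
        labels=("R1", "R2", "R3", "R4"),
        centroids=np.array([[0, 0, 0], [10, 0, 0], [20, 0, 0], [30, 0, 0]], dtype=float),
        networks=("net1", "net1", "net1", "net1"),
    )


@pytest.fixture
def line_sc(line_atlas) -> ConnMatrix:
    """Chain edges at SC 0.5 plus a weak direct R1-R4 edge at 0.1."""
    sc = np.zeros((4, 4))
    for i, j, w in [(0, 1, 0.5), (1, 2, 0.5), (2, 3, 0.5), (0, 3, 0.1)]:
        sc[i, j] = sc[j, i] = w
    return ConnMatrix(values=sc, kind="SC", labels=line_atlas.labels)


@pytest.fixture
def line_dist(line_atlas) -> ConnMatrix:
    return usfc.euclidean_distances(line_atlas)


def make_random_problem(rng: np.random.Generator, n: int, density: float):
    """A random distance matrix + sparse SC for routing oracle tests."""
    pts = rng.uniform(0, 100, size=(n, 3))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    sc = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.uniform(size=iu.size) < density
    w = rng.uniform(0.05, 1.0, size=iu.size)
    sc[iu[keep], ju[keep]] = w[keep]
    sc = sc + sc.T
    return d, sc


@pytest.fixture(scope="session")
def small_dataset():
    """A 20-region, 5-subject synthetic cohort reused across tests."""
    cfg = usfc.SynthConfig(n_regions=20, n_networks=4, n_subjects=5, seed=11)
    atlas, subjects, truth = usfc.generate_dataset(cfg)
    return cfg, atlas, subjects, truth


@pytest.fixture(scope="session")
def cohort_analysis():
    """Factory: full analysis of the default-condition cohort for a seed.

    Results are cached per seed because several recovery checks share them.
    """
    cache: dict[int, dict] = {}

    def run(seed: int) -> dict:
        if seed in cache:
            return cache[seed]
        cfg = usfc.SynthConfig(seed=seed)
        atlas, subjects, truth = usfc.generate_dataset(cfg)
        D = usfc.euclidean_distances(atlas)
        tables = [usfc.route_all_pairs(s, D) for s in subjects]
        usfc_list = [usfc.accumulate_usfc(t, s.fc) for t, s in zip(tables, subjects)]
        group = usfc.group_usfc(usfc_list)
        top = usfc.top_k_edges(group, 10)
        nets = usfc.network_summary(usfc_list, atlas)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # modal ties are expected
            consistent = usfc.modal_routes(tables, subjects)
        coupling = usfc.coupling_by_step(consistent)
        cache[seed] = {
            "config": cfg,
            "atlas": atlas,
            "subjects": subjects,
            "truth": truth,
            "tables": tables,
            "usfc_list": usfc_list,
            "group": group,
            "top_edges": top,
            "networks": nets,
            "consistent": consistent,
            "coupling": coupling,
        }
        return cache[seed]

    return run
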