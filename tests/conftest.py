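"""Shared fixtures: cohorts, GRMs and synthetic frames used across the suite."""

import numpy as np
import pytest

from pigtme import quantgen, simdata


@pytest.fixture(scope="session")
def small_cfg():
    return simdata.SimConfig(seed=42, n_individuals=300, n_markers=2000)


@pytest.fixture(scope="session")
def small_geno(small_cfg):
    return simdata.simulate_genotypes(small_cfg, np.random.default_rng(42))


@pytest.fixture(scope="session")
def small_grm(small_geno):
    fgeno = quantgen.maf_filter(small_geno)
    _, grm = quantgen.build_grm(fgeno)
    grm.eig()
    return fgeno, grm


@pytest.fixture(scope="session")
def cohort800():
    """Default-scale cohort (n=800, m=10,000, 25 sires) with its GRM, built once."""
    cfg = simdata.SimConfig(seed=7)
    geno = simdata.simulate_genotypes(cfg, np.random.default_rng(7))
    fgeno = quantgen.maf_filter(geno)
    _, grm = quantgen.build_grm(fgeno)
    grm.eig()
    return cfg, geno, fgeno, grm


def make_slab_frame(cfg, slab=(60, 120, 100, 220), distance=1.0):
    """A rectangular slab at uniform distance on the floor plane."""
    rows, cols = cfg.image_shape
    dist = np.full((rows, cols), cfg.camera_height)
    r0, r1, c0, c1 = slab
    dist[r0:r1, c0:c1] = distance
    return simdata.DepthFrame(
        distance_map=dist,
        color_image=simdata.encode_color(dist, cfg.camera_height),
        frame_index=0,
    )


@pytest.fixture(scope="session")
def slab_frame():
    cfg = simdata.SimConfig(seed=0)
    return cfg, make_slab_frame(cfg)
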