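"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import extrudex as x


@pytest.fixture(scope="session")
def wt_bundle():
    """One wild-type G2/M simulation with all derived objects."""
    ann = x.make_genome(40, 300_000, seed=0)
    barriers = x.derive_barriers(ann, "WT_G2M")
    cfg = x.SimulationConfig(seed=0)
    snaps = x.simulate_extrusion(ann, barriers, cfg)
    raw = x.render_contact_map(snaps, ann, cfg)
    return {
        "annotation": ann,
        "barriers": barriers,
        "config": cfg,
        "snapshots": snaps,
        "raw": raw,
        "norm": x.vc_sqrt_normalize(raw),
        "tracks": x.render_tracks(snaps, ann, "WT_G2M"),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_symmetric_matrix(rng, n, scale=20.0):
    m = rng.poisson(scale, size=(n, n)).astype(float)
    m = np.triu(m)
    return m + np.triu(m, 1).T
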