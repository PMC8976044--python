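"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from ringrec.io_formats import ParticleRecord, ParticleTable
from ringrec.synthetic_data import (
    CollectionSpec,
    RingSpec,
    make_toy_ring_volume,
    simulate_particles,
)

# Ring scaled so every blob is >= ~1.5 voxels wide and the ring plus 4 sigma
# of blob support stays inside the grid.
SMALL_GRID = 48
SMALL_PIXEL = 3.2
SMALL_RADIUS = 38.0


@pytest.fixture(scope="session")
def small_ring_spec() -> RingSpec:
    return RingSpec(ring_radius=SMALL_RADIUS)


@pytest.fixture(scope="session")
def small_ring(small_ring_spec):
    """(volume, ground-truth model) on a 48^3 grid."""
    return make_toy_ring_volume(small_ring_spec, SMALL_GRID, SMALL_PIXEL, seed=1)


@pytest.fixture(scope="session")
def small_sim(small_ring):
    """40-particle noisy simulated stack with ground-truth table."""
    volume, _ = small_ring
    spec = CollectionSpec(n_particles=40, snr=1.0, seed=7, shift_range=3.0)
    return simulate_particles(volume, spec)


@pytest.fixture()
def ten_row_table() -> ParticleTable:
    records = [
        ParticleRecord(
            image_name="stack.mrcs",
            image_index=i,
            rot=17.0 * i - 80.0,
            tilt=10.0 + 15.0 * i,
            psi=-160.0 + 33.0 * i,
            shift_x=0.25 * i,
            shift_y=-0.5 * i,
            defocus_u=15000.0 + 100.0 * i,
            defocus_v=16000.0 + 100.0 * i,
            astig_angle=5.0 * i,
            pixel_size=5.548,
            group_id=i % 4,
            subunit_index=None,
            extras={"_rlnRandomSubset": str(1 + i % 2)},
        )
        for i in range(10)
    ]
    return ParticleTable.from_records(records, provenance="fixture bin4")
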