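"""Shared fixtures: small simulated maps with planted, known structure."""

import numpy as np
import pytest

import hic3d as h


@pytest.fixture(scope="session")
def tad_fixture():
    """Single 10 Mb chromosome tiled by ten 1 Mb TADs at 50 kb bins."""
    asm = h.GenomeAssembly(("chr1",), (10_000_000,))
    tads = [
        h.GenomicInterval("chr1", i * 1_000_000, (i + 1) * 1_000_000)
        for i in range(10)
    ]
    cfg = h.SimulationConfig(
        asm, 50_000, depth=1e6, seed=1, tads=tads, trans_rate=0.0
    )
    matrix, truth = h.simulate_contacts(cfg)
    return matrix, truth


@pytest.fixture(scope="session")
def loop_fixture():
    """3 Mb chromosome at 5 kb bins with 20 planted fold-8 loops."""
    asm = h.GenomeAssembly(("chr1",), (3_000_000,))
    loops = []
    for k in range(20):
        i = 30 + k * 25
        d = 20 + (k % 5) * 10
        loops.append(
            (
                h.GenomicInterval("chr1", i * 5000, (i + 1) * 5000),
                h.GenomicInterval("chr1", (i + d) * 5000, (i + d + 1) * 5000),
            )
        )
    cfg = h.SimulationConfig(
        asm, 5_000, depth=1e6, seed=7, loops=loops, trans_rate=0.0
    )
    matrix, truth = h.simulate_contacts(cfg)
    return matrix, truth


@pytest.fixture(scope="session")
def null_map_5kb():
    """Pure-decay 3 Mb chromosome at 5 kb bins (no TADs/loops/SVs)."""
    asm = h.GenomeAssembly(("chr1",), (3_000_000,))
    cfg = h.SimulationConfig(asm, 5_000, depth=1e6, seed=8, trans_rate=0.0)
    matrix, _ = h.simulate_contacts(cfg)
    return matrix


@pytest.fixture(scope="session")
def insulator_scenario():
    return h.simulate_insulator_scenario(seed=0)


def random_loops(n, seed, resolution=5_000, chrom="chr1", n_bins=400):
    """n random bin-aligned loops on one chromosome (helper, not fixture)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        i = int(rng.integers(0, n_bins - 10))
        j = int(i + rng.integers(2, 10))
        out.append(
            h.Loop(
                h.GenomicInterval(chrom, i * resolution, (i + 1) * resolution),
                h.GenomicInterval(chrom, j * resolution, (j + 1) * resolution),
                observed=float(rng.integers(1, 100)),
                expected_p=float(rng.uniform(1e-8, 1e-4)),
                p_value=float(rng.uniform(0, 0.01)),
                q_value=float(rng.uniform(0, 0.05)),
                sample_id=f"S{int(rng.integers(0, 3))}",
            )
        )
    return out
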