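import numpy as np
import pytest

from eccell.ecdna_sim import (
    SimReadConfig, SimStructureConfig, simulate_ecdna_structures, simulate_library,
)

MINI_SIZES = {"chrT1": 6_000_000, "chrT2": 6_000_000}


@pytest.fixture(scope="session")
def mini_library(tmp_path_factory):
    """One small simulated library shared across detector/assignment tests:
    three planted circles (one of them two-segment, one spanning both
    chromosomes) at 12x local depth over a 4x background, 24 barcoded cells,
    the first 8 barcodes carrying circle 0."""
    workdir = tmp_path_factory.mktemp("mini_library")
    structures = simulate_ecdna_structures(SimStructureConfig(
        n_circles=3, size_range=(150_000, 400_000), max_segments_per_circle=2,
        reference=MINI_SIZES, segment_margin=100_000, seed=11))
    barcodes = [f"BC{i:03d}" for i in range(24)]
    members = barcodes[:8]
    bam = str(workdir / "library.bam")
    simulate_library(structures, SimReadConfig(
        background_depth=4.0, circle_local_depth=12.0,
        barcodes=barcodes, circle_membership={structures[0].id: members},
        seed=12,
    ), MINI_SIZES, bam)
    return {
        "bam": bam,
        "truth": structures,
        "sizes": MINI_SIZES,
        "barcodes": barcodes,
        "members": members,
    }
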