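import numpy as np
import pysam
import pytest

from binsift import SimulationConfig, generate_dataset
from binsift.scg import ScgCollection


@pytest.fixture(scope="session")
def toy_collection():
    return ScgCollection("toy", ("g1", "g2", "g3", "g4"))


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down scenario for fast unit tests (2 contaminants, 4 libraries)."""
    return SimulationConfig(
        seed=11,
        host_length=300_000,
        n_contaminants=2,
        contaminant_lengths=(80_000, 80_000),
        n_core_libraries=2,
        n_aux_libraries=2,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """The reference scenario: 2 Mbp host + 3 x 0.5 Mbp contaminants, 3+6 libraries."""
    return generate_dataset(SimulationConfig(seed=1))


@pytest.fixture
def bam_factory(tmp_path):
    """Build a coordinate-sorted, indexed BAM from (ref, pos, length) reads."""

    def make(references: dict[str, int], reads: list[tuple[str, int, int]],
             name: str = "reads", duplicate_every_read: bool = False):
        order = list(references)
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": l} for n, l in references.items()],
        }
        if duplicate_every_read:
            reads = [r for r in reads for _ in range(2)]
        unsorted = tmp_path / f"{name}.unsorted.bam"
        with pysam.AlignmentFile(str(unsorted), "wb", header=header) as bam:
            for i, (ref, pos, length) in enumerate(reads):
                a = pysam.AlignedSegment(bam.header)
                a.query_name = f"read_{i}"
                a.query_sequence = "A" * length
                a.query_qualities = pysam.qualitystring_to_array("I" * length)
                a.reference_id = order.index(ref)
                a.reference_start = pos
                a.mapping_quality = 30
                a.cigartuples = [(0, length)]
                a.flag = 0
                bam.write(a)
        out = tmp_path / f"{name}.bam"
        pysam.sort("-o", str(out), str(unsorted))
        pysam.index(str(out))
        return out

    return make


def brute_force_depth(references: dict[str, int],
                      reads: list[tuple[str, int, int]]) -> dict[str, np.ndarray]:
    """Independent per-base depth oracle for synthetic read placements."""
    depth = {name: np.zeros(length, dtype=int) for name, length in references.items()}
    for ref, pos, length in reads:
        depth[ref][pos : pos + length] += 1
    return depth
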