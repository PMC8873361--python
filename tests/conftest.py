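"""Shared fixtures: a deterministic synthetic study reused across test modules."""

import numpy as np
import pytest

from editome.io_formats import MatureArm, Precursor
from editome.pipeline import run_cohort
from editome.synthetic import default_spec, simulate_cohort, simulate_reference

MASTER_SEED = 11
REFERENCE_SEED = 7


def random_seq(seed: int, n: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def toy_precursor() -> Precursor:
    """An 80-nt hairpin with arms at 6-27 and 50-71 on the plus strand."""
    return Precursor(
        id="mirX",
        seq=random_seq(3, 80),
        chrom="chr1",
        g_start=101,
        g_end=180,
        strand="+",
        arms=(MatureArm("mirX-5p", 6, 27), MatureArm("mirX-3p", 50, 71)),
    )


@pytest.fixture(scope="session")
def reference():
    """Ten hairpins with one planted event of every category plus decoys."""
    spec = default_spec(group_sizes={"HD-PC": 4, "PC": 4}, depth=400)
    return simulate_reference(spec, REFERENCE_SEED)


@pytest.fixture(scope="session")
def cohort(reference):
    groups, reads, truth = simulate_cohort(reference, MASTER_SEED)
    return groups, reads, truth


@pytest.fixture(scope="session")
def cohort_results(reference, cohort):
    """Full pipeline run over the synthetic cohort (matrix + per-sample calls)."""
    groups, reads, _ = cohort
    matrix, samples = run_cohort(
        reads,
        groups,
        reference.precursors,
        genome=reference.genome,
        snps=reference.snp_records,
    )
    return matrix, samples
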