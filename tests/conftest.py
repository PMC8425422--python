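from __future__ import annotations

import numpy as np
import pytest

from hla_cohort_qc import simulate
from hla_cohort_qc.reference import AlleleReference, select_genes


@pytest.fixture
def tiny_ref_fasta(tmp_path):
    """Hand-written 3-record reference fixture."""
    path = tmp_path / "ref.fasta"
    path.write_text(
        ">A*01:01:01:01\nACGTACGTACGTACGTACGT\n"
        ">A*02:01\nTTTTACGTACGTACGTCCCC\n"
        ">B*07:02:01\nGGGGACGTACGTACGTAAAA\n"
    )
    return path


@pytest.fixture(scope="session")
def small_ref() -> AlleleReference:
    """Synthetic 6-gene reference, 12 groups per gene, 300 bp alleles."""
    rng = np.random.default_rng(42)
    return simulate.synthetic_reference(rng, groups_per_gene=12, seq_len=300)


@pytest.fixture(scope="session")
def small_ref5(small_ref) -> AlleleReference:
    return select_genes(small_ref, 5)


@pytest.fixture(scope="session")
def small_table(small_ref) -> simulate.FrequencyTable:
    return simulate.synthetic_frequency_table(small_ref)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory, small_ref, small_table):
    """Seeded 4-individual paired-end cohort at reduced depth.

    Returns (cohort_dir, truth).  Shared across tests; treat as read-only.
    """
    out = tmp_path_factory.mktemp("cohort")
    params = simulate.SimParams(
        n_individuals=4,
        samples_min=1,
        samples_max=2,
        reads_min=4000,
        reads_max=6000,
        error_rate=0.005,
    )
    truth = simulate.simulate_cohort(params, small_table, small_ref, 11, out)
    return out, truth
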