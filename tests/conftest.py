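import numpy as np
import pytest

from mitoscan import io_and_matrix as iom
from mitoscan import synthetic_data as sim


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 25-sample cohort on a 3 kb genome with one strong
    planted site, used across modules."""
    cfg = sim.SimConfig(
        genome_length=3000,
        seed=5,
        n_group={"F": 10, "NF": 15},
        private_mutation_rate=2.0,
        n_haplogroups=8,
        planted_sites=[sim.PlantedSite(1500, "A", {"F": 0.9, "NF": 0.2})],
    )
    reference, seqs, truth, tree = sim.generate_cohort(cfg)
    return cfg, reference, seqs, truth, tree


@pytest.fixture(scope="session")
def cohort_files(small_cohort, tmp_path_factory):
    """The small cohort written out as FASTA/VCF/TSV/JSON files."""
    _, reference, seqs, truth, tree = small_cohort
    outdir = tmp_path_factory.mktemp("cohort")
    return sim.write_cohort_files(reference, seqs, truth, tree, outdir)


def make_seqs(reference, bases_by_sample, groups):
    """Hand-build MitoSequence lists for toy alignments."""
    return [
        iom.MitoSequence(sample_id=sid, bases=b, group=groups[sid])
        for sid, b in bases_by_sample.items()
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
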