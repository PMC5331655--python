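import numpy as np
import pytest

from teconsex.repeat_catalog import TEInstance
from teconsex.synthetic_data import FamilySpec, SimConfig, simulate_dataset


def make_instance(
    instance_id="i1",
    chrom="chr1",
    start=100,
    end=600,
    strand="+",
    family="FamA",
    te_class="LTR",
    scaled_score=800,
    length_bp=None,
):
    return TEInstance(
        instance_id=instance_id,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        family=family,
        te_class=te_class,
        scaled_score=scaled_score,
        length_bp=length_bp if length_bp is not None else end - start,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 3-species dataset shared by file-level and pipeline tests.

    Two well-separated families: an old, retained, expression-conserved LTR
    family and a young, poorly retained SINE family with near-zero
    expression correlation.
    """
    config = SimConfig(
        seed=42,
        n_species=3,
        genome_length=1_500_000,
        families=[
            FamilySpec("OldLTR", "LTR", 150, 20.0, 0.05, 0.4, 0.7),
            FamilySpec("YoungSINE", "SINE", 150, 4.0, 0.30, 0.4, 0.05),
        ],
        n_reads_per_replicate=60_000,
        replicates_per_species=[2, 1, 1],
        lncrna_count=24,
        coding_gene_count=6,
    )
    out = tmp_path_factory.mktemp("smalldata")
    return simulate_dataset(config, out)
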