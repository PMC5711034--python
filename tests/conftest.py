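import pytest

from allosim.synthetic_data import CohortSpec, generate_pair


@pytest.fixture(scope="session")
def tiny_spec():
    """Small, fast cohort spec with deterministic (sd=0) variant counts."""
    return CohortSpec(
        n_genes=30,
        gene_length_range=(60, 120),
        mean_nssnp={"MRD": 10.0, "MUD": 20.0},
        sd_nssnp={"MRD": 0.0, "MUD": 0.0},
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_pair(tiny_spec, tmp_path_factory):
    return generate_pair(tiny_spec, 0, tmp_path_factory.mktemp("pair") / "pair_0000")
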