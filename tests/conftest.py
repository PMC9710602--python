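import pytest

from asrnadesign.synthetic import SyntheticGenomeSpec, make_genome


@pytest.fixture(scope="session")
def clean_genome():
    """Six pairwise-dissimilar genes: no off-targets exist by construction."""
    return make_genome(SyntheticGenomeSpec(n_genes=6, seed=7))


@pytest.fixture(scope="session")
def sd_dup_genome():
    """Gene 1's SD/start region duplicated at an extra locus: the round-1
    window is duplicated but the stepped round-2 window is not."""
    return make_genome(
        SyntheticGenomeSpec(
            n_genes=6, seed=11, duplicate_pairs=[(0, "sd_start_region")]
        )
    )


@pytest.fixture(scope="session")
def full_dup_genome():
    """Gene 1 duplicated whole with 30 nt flanks: no nearby window escapes."""
    return make_genome(
        SyntheticGenomeSpec(
            n_genes=6, seed=11, duplicate_pairs=[(0, "whole_gene_with_flanks")]
        )
    )
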