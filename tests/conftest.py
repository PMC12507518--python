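"""Shared fixtures: random motifs and a session-scoped planted dataset."""

import numpy as np
import pytest

from motifdelta.fixtures import FixtureSpec, plant_sites_and_variants
from motifdelta.motif_io import DI_ALPHABET, MONO_ALPHABET, PSPM
from motifdelta.variant_scoring import prepare_motifs, score_variants


def random_pspm(rng, length, alphabet_size=4, name="m"):
    """Generic random PSPM with Dirichlet columns (no IC tuning)."""
    alphabet = MONO_ALPHABET if alphabet_size == 4 else DI_ALPHABET
    probs = rng.dirichlet(np.full(alphabet_size, 0.5), size=length)
    return PSPM(name=name, probs=probs, alphabet=alphabet)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def planted(tmp_path_factory):
    """Planted-site dataset at the generator's default study conditions.

    20 motifs x 25 sites each -> 500 site-disrupting SNVs plus 500
    background SNVs on a 100 kb contig.
    """
    out = tmp_path_factory.mktemp("planted")
    return plant_sites_and_variants(out, FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def planted_diff(planted):
    """probNorm/max-pooled Diff matrix of the planted dataset."""
    prepared = prepare_motifs(planted.motifs, mode="probnorm")
    return score_variants(str(planted.vcf), str(planted.fasta), prepared, pooling="max")
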