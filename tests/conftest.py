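import pytest
from hypothesis import settings

from amplihap.core import GenotypeProfile, SegmentGenotype
from amplihap.synthetic import SimConfig, sim_study

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_profile(profile_id, pairs):
    """Build a profile from {segment_id: (a, b) or None}."""
    return GenotypeProfile(
        profile_id,
        {seg: SegmentGenotype(seg, pair) for seg, pair in pairs.items()},
    )


@pytest.fixture(scope="session")
def study():
    """Default-scale synthetic study: 141 accessions, 72 base genotypes,
    19 reference-panel segments, near-even haplotype frequencies so that
    chance allele sharing across all segments is negligible."""
    return sim_study(SimConfig(dirichlet_conc=2.0), seed=1)


@pytest.fixture(scope="session")
def study_skewed():
    """Study-condition frequencies (skewed Dirichlet, one common
    haplotype plus rare tail)."""
    return sim_study(SimConfig(), seed=7)
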