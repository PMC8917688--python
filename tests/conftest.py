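import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from contigscout.fixtures import GenomeSpec, mock_community
from contigscout.taxonomy import TaxLineage

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(("A", "C", "G", "T"), size=length, p=probs))


@pytest.fixture(scope="session")
def community_specs():
    """Two prokaryotes with well-separated composition plus one sparse,
    low-GC eukaryote-like genome."""
    return [
        GenomeSpec(
            "GenomeA",
            TaxLineage.make(domain="Bacteria", phylum="PhylA",
                            genus="Alphagenus", species="Alphagenus primus"),
            genome_length=60_000, target_gc=30.0, gene_density=1.0,
            coverage=10.0, seed=101,
        ),
        GenomeSpec(
            "GenomeB",
            TaxLineage.make(domain="Bacteria", phylum="PhylB",
                            genus="Betagenus", species="Betagenus duo"),
            genome_length=60_000, target_gc=60.0, gene_density=1.0,
            coverage=30.0, seed=102,
        ),
        GenomeSpec(
            "EukaryC",
            TaxLineage.make(domain="Eukaryota", phylum="PhylC",
                            genus="Gammamyces", species="Gammamyces tres"),
            genome_length=60_000, target_gc=42.0, gene_density=0.1,
            coverage=5.0, seed=103,
        ),
    ]


@pytest.fixture(scope="session")
def small_community(community_specs, tmp_path_factory):
    """Unfragmented three-genome community with all sidecar files written."""
    out = tmp_path_factory.mktemp("community")
    return mock_community(
        community_specs, out, fragment=False, n_hits=10,
        identity_mean=85.0, identity_sd=5.0, seed=7,
    )
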