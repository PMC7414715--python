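import numpy as np
import pytest

from parafates.alignio import FamilyAlignment, GeneRecord, extract_paralog_pairs
from parafates.simulate import SimConfig, simulate_family


@pytest.fixture(scope="session")
def default_family():
    """Default simulated study family: 12 species, 4 independent duplications."""
    cfg = SimConfig(seed=11)
    aln, mapping, truth = simulate_family(cfg)
    return aln, mapping, truth


@pytest.fixture(scope="session")
def default_pairs(default_family):
    aln, mapping, _ = default_family
    return extract_paralog_pairs(aln, mapping)


@pytest.fixture(scope="session")
def default_rows(default_family, default_pairs):
    from parafates.scoring import score_quartets

    aln, _, _ = default_family
    return score_quartets(aln, default_pairs, mode="parsimony", rng=0)


def make_alignment(seqs: dict[str, str], species: dict[str, str] | None = None):
    species = species or {}
    return FamilyAlignment(
        [GeneRecord(g, species.get(g, ""), s) for g, s in seqs.items()]
    )


@pytest.fixture
def quartet_alignment():
    """Hand-built 4-gene alignment with known pattern composition."""
    # columns 1-14: Q,Q,const,const,R,R,R,S,t,t,u,degenerate(AAAT),gap,X
    a = "AACCAAGLADKA-A"
    b = "AACCTTHMTERAAC"
    c = "TTCCAAGMADSACD"
    d = "TTCCTTHLCFRTDX"
    return make_alignment(
        {"x_1": a, "x_2": b, "y_1": c, "y_2": d},
        {"x_1": "spx", "x_2": "spx", "y_1": "spy", "y_2": "spy"},
    )
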