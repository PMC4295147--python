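import pytest

from plasnet.synthio import FamilySpec, RepliconSpec, SimConfig, simulate_plasmidome


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic plasmidome shared by fast tests.

    Two plasmids + one chromosome, two planted families (one spanning the
    chromosome), 60 background genes.
    """
    cfg = SimConfig(
        seed=11,
        replicons=(
            RepliconSpec("p1", "plasmid", 20, (100, 180)),
            RepliconSpec("p2", "plasmid", 20, (100, 180)),
            RepliconSpec("chr", "chromosome", 20, (100, 180)),
        ),
        families=(
            FamilySpec("famA", (("p1", 2), ("p2", 2)), target_identity=0.8),
            FamilySpec("famB", (("p1", 2), ("chr", 2)), target_identity=0.95),
        ),
    )
    return simulate_plasmidome(cfg)


@pytest.fixture(scope="session")
def small_rset(small_sim):
    return small_sim.replicon_set


@pytest.fixture(scope="session")
def small_edges(small_sim):
    """Filtered, symmetrized, classified edges of the small plasmidome."""
    from plasnet import network, similarity

    rset = small_sim.replicon_set
    hits = similarity.all_vs_all(rset.proteins)
    retained = similarity.filter_hits(
        hits, similarity.FilterCriteria(), rset.lengths()
    )
    return network.classify_edges(similarity.symmetrize(retained), rset)
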