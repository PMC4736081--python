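import random
import warnings

import pytest

import gbcrispr as gb
from gbcrispr.molecules import canonical_rotation
from tests.conftest import (
    brute_force_cycles,
    random_circular_with_sites,
    random_fragments,
)

CFG = gb.default_config()
BSAI = CFG.bsai

OH_POOL = ["GGAG", "AATG", "GCTT", "CGCT", "TACT"]


@pytest.mark.parametrize("seed", range(6))
def test_digest_ligate_round_trip(seed):
    rng = random.Random(seed)
    m = random_circular_with_sites(rng, BSAI)
    products = gb.ligate(gb.digest(m, BSAI))
    assert any(p == m for p in products)


def test_non_matching_overhangs_no_circle():
    a = gb.Fragment(core="AAAA", left_overhang="GGAG", right_overhang="AATG")
    b = gb.Fragment(core="CCCC", left_overhang="GCTT", right_overhang="CGCT")
    assert gb.ligate([a, b]) == []


def test_designed_chain_excludes_decoy():
    """a->b->c->d->a closes; a decoy with unmatched overhangs is left out."""
    oh = ["GGAG", "AATG", "GCTT", "CGCT"]
    frags = [
        gb.Fragment(core="AAAAAAAA", left_overhang=oh[0], right_overhang=oh[1]),
        gb.Fragment(core="CCCCCCCC", left_overhang=oh[1], right_overhang=oh[2]),
        gb.Fragment(core="GTGTGTGT", left_overhang=oh[2], right_overhang=oh[3]),
        gb.Fragment(core="TTTTTTTT", left_overhang=oh[3], right_overhang=oh[0]),
        gb.Fragment(core="ACACACAC", left_overhang="TACT", right_overhang="CCAT"),
    ]
    products = gb.ligate(frags)
    assert len(products) == 1
    assert products[0] == gb.DNAMolecule(
        "expect",
        "".join(f.left_overhang + f.core for f in frags[:4]),
        gb.CIRCULAR,
    )
    assert brute_force_cycles(frags) == {products[0].canonical()}


@pytest.mark.parametrize("seed", range(10))
def test_cycle_enumeration_matches_brute_force(seed):
    rng = random.Random(seed)
    frags = random_fragments(rng, rng.randrange(3, 7), OH_POOL)
    impl = {
        p.canonical()
        for p in gb.ligate(frags, product_cap=100_000, cycle_cap=10)
    }
    assert impl == brute_force_cycles(frags)


def test_ligate_conserves_nucleotides():
    rng = random.Random(11)
    m = random_circular_with_sites(rng, BSAI, min_sites=2)
    frags = gb.digest(m, BSAI)
    products = gb.ligate(frags)
    original = [p for p in products if p == m]
    assert original and len(original[0]) == len(m)


def test_product_cap_raises():
    # many mutually compatible fragments with one shared overhang explode
    frags = [
        gb.Fragment(core=f"{'A' * i}CC", left_overhang="GGAG", right_overhang="GGAG")
        for i in range(2, 12)
    ]
    with pytest.raises(gb.LigationCapError):
        gb.ligate(frags, product_cap=5)


def test_palindromic_overhang_warns():
    f = gb.Fragment(core="AAAA", left_overhang="ACGT", right_overhang="ACGT")
    with pytest.warns(UserWarning, match="palindromic"):
        gb.ligate([f])


def test_maximal_linear_paths():
    a = gb.Fragment(core="AAAA", right_overhang="AATG")  # blunt left
    b = gb.Fragment(core="CCCC", left_overhang="AATG", right_overhang="GCTT")
    c = gb.Fragment(core="GGGG", left_overhang="GCTT")  # blunt right
    products = gb.ligate([a, b, c], require_circular=False)
    linear = [p for p in products if p.topology == gb.LINEAR]
    assert len(linear) == 1
    assert linear[0].sequence == "AAAA" + "AATG" + "CCCC" + "GCTT" + "GGGG"


# --------------------------------------------------------- golden gate


def test_golden_gate_fixture_cassette(kit, config):
    """Promoter + target duplex + scaffold chain into the alpha backbone;
    product length is backbone plus the sum of the released inserts."""
    parts = kit["parts"]
    alpha1 = kit["alpha1"]
    duplex = gb.domesticate_target("G" + "ATC" * 6 + "A", "D", config)
    products = gb.golden_gate(
        [parts["polIII_promoter"].molecule, parts["scaffold_D"].molecule],
        alpha1.molecule,
        config.bsai,
        extra_fragments=(duplex.to_fragment(),),
    )
    assert len(products) == 1
    product = products[0]
    assert any(a[0] == "backbone" for a in product.annotations)
    assert not gb.find_sites(product, config.bsai)
    # length accounting: each cargo contributes its top_length, plus backbone
    frags = [f for f in gb.digest(alpha1.molecule, config.bsai) if not f.circular]
    backbone = max(frags, key=lambda f: len(f.core))
    expected = (
        backbone.top_length
        + duplex.to_fragment().top_length
        + len(gb.release_insert(parts["polIII_promoter"].molecule, config.bsai)) - 4
        + len(gb.release_insert(parts["scaffold_D"].molecule, config.bsai)) - 4
    )
    assert len(product) == expected


def test_golden_gate_broken_chain_fails(kit, config):
    parts = kit["parts"]
    duplex = gb.domesticate_target("G" + "ATC" * 6 + "A", "D", config)
    with pytest.raises(gb.AssemblyError, match="unmatched"):
        gb.golden_gate(
            [parts["polIII_promoter"].molecule],  # scaffold omitted
            kit["alpha1"].molecule,
            config.bsai,
            extra_fragments=(duplex.to_fragment(),),
        )


def test_golden_gate_rejects_undigested_destination(kit, config):
    plain = gb.DNAMolecule("p", "ACGT" * 200, gb.CIRCULAR)
    with pytest.raises(gb.AssemblyError, match="site"):
        gb.golden_gate([], plain, config.bsai)


def test_internal_site_product_filtered(config):
    """A part retaining an internal assembly-enzyme site never appears in
    the stable product set."""
    fx = gb.FixtureConfig(seed=5)
    alpha1 = gb.make_vector("alpha", fx, config, position=1)
    # cargo chain GGAG->CGCT with an internal BsaI recognition
    bad = gb.Fragment(
        core="AAAA" + config.bsai.recognition + "AAAA",
        left_overhang="GGAG",
        right_overhang="CGCT",
    )
    with pytest.raises(gb.AssemblyError):
        gb.golden_gate([], alpha1.molecule, config.bsai, extra_fragments=(bad,))


def test_golden_gate_products_lack_enzyme_sites_both_strands(kit, config):
    duplex = gb.domesticate_target("G" + "TAC" * 6 + "T", "D", config)
    products = gb.golden_gate(
        [kit["parts"]["polIII_promoter"].molecule,
         kit["parts"]["scaffold_D"].molecule],
        kit["alpha1"].molecule,
        config.bsai,
        extra_fragments=(duplex.to_fragment(),),
    )
    for p in products:
        assert gb.find_sites(p, config.bsai) == []
        assert gb.find_sites(p.reverse_complement(), config.bsai) == []
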