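import random

import pytest

import gbcrispr as gb
from tests.conftest import brute_force_scan

CFG = gb.default_config()


# ------------------------------------------------------------- scanning


def test_scan_single_planted_target():
    g = gb.DNAMolecule("g", "GAAAAAAAAAAAAAAAAAAATGGT")
    hits = gb.scan_targets(g, require_5prime_G=True)
    assert [(t.protospacer, t.pam, t.strand) for t in hits] == [
        ("GAAAAAAAAAAAAAAAAAAA", "TGG", "+")
    ]
    assert hits[0].gc_pct == 5.0


def test_scan_at_only_genome_empty():
    g = gb.DNAMolecule("g", "ATAT" * 20)
    assert gb.scan_targets(g, require_5prime_G=True) == []


def test_scan_matches_brute_force_oracle():
    rng = random.Random(17)
    seq = "".join(rng.choice("ACGT") for _ in range(3000))
    g = gb.DNAMolecule("g", seq)
    impl = {
        (t.protospacer, t.pam, t.strand, t.start)
        for t in gb.scan_targets(g, require_5prime_G=True)
    }
    assert impl == brute_force_scan(seq, require_5prime_G=True)


def test_gc_filter_inclusive_bounds():
    g = gb.DNAMolecule("g", "GGGGGAAAAAGGGGGAAAAATGGT")  # 50% GC target at 0
    hits = gb.scan_targets(g, gc_min=50, gc_max=50)
    assert hits and all(t.gc_pct == 50.0 for t in hits)
    assert gb.scan_targets(g, gc_min=55) == []


def test_diagnostic_site_requires_cut_overlap():
    spe = CFG.enzyme("SpeI")
    # SpeI at protospacer offsets 14..20: contains the cut at 17
    proto_hit = "G" + "A" * 13 + "ACTAGT"
    g1 = gb.DNAMolecule("g", "CC" + proto_hit + "TGG" + "CCCC")
    hits = gb.scan_targets(g1, enzyme_panel=[spe], require_diagnostic_site=True)
    assert [t.protospacer for t in hits if t.strand == "+"] == [proto_hit]
    (t,) = [t for t in hits if t.strand == "+"]
    assert t.diagnostic_sites == [("SpeI", 2 + 14)]
    # same site fully 5' of the cut (offsets 1..7) does not qualify
    proto_miss = "G" + "ACTAGT" + "A" * 13
    g2 = gb.DNAMolecule("g", "CC" + proto_miss + "TGG" + "CCCC")
    assert (
        gb.scan_targets(g2, enzyme_panel=[spe], require_diagnostic_site=True) == []
    )


def test_minus_strand_cut_coordinate():
    # plant a + strand target, scan its revcomp context on the minus strand
    proto = "G" + "AC" * 9 + "T"
    plus = "TT" + proto + "AGG" + "TTTT"
    g = gb.DNAMolecule("g", gb.revcomp(plus))
    hits = [t for t in gb.scan_targets(g) if t.protospacer == proto]
    assert len(hits) == 1
    t = hits[0]
    assert t.strand == "-"
    # the protospacer sits at [start, start+20) read on the minus strand,
    # with the PAM immediately 5' of it in plus coordinates
    assert gb.revcomp(g.sequence[t.start : t.start + 20]) == proto
    assert gb.revcomp(g.sequence[t.start - 3 : t.start]) == t.pam
    # cut 3 bp from the PAM-proximal end in plus coordinates
    assert t.genome_cut == t.start + 3


# -------------------------------------------------------- domesticator


def test_domesticator_modes_use_configured_fusion_sites(config):
    d = gb.domesticate_target("G" * 20, "D", config)
    m = gb.domesticate_target("G" * 20, "M", config)
    assert d.left_fusion == m.left_fusion == config.syntax_table["B3c"][0]
    assert d.right_fusion == config.syntax_table["B5c"][1]
    assert m.right_fusion == config.syntax_table["B5d"][1]
    p = gb.domesticate_target("G" * 20, "poly:2", config)
    assert p.left_fusion == config.trna_seq[-4:]
    assert p.right_fusion == config.scaffold_seq[:4]


def test_annealing_reproduces_protrusions(config):
    duplex = gb.domesticate_target("G" + "CTA" * 6 + "C", "D", config)
    frag = gb.anneal(duplex.fwd_oligo, duplex.rev_oligo)
    assert frag.left_overhang == duplex.left_fusion
    assert frag.right_overhang == duplex.right_fusion
    assert frag.core == duplex.protospacer


def test_policy_5g(config):
    with pytest.raises(gb.DesignError):
        gb.domesticate_target("A" + "C" * 19, "D", config, policy_5G="reject")
    duplex = gb.domesticate_target("A" + "C" * 19, "D", config, policy_5G="substitute")
    assert duplex.protospacer.startswith("G")
    assert duplex.substituted_5prime_g


def test_domesticator_rejects_internal_assembly_site(config):
    with pytest.raises(gb.DomesticationError) as err:
        gb.domesticate_target("G" + "GGTCTC" + "A" * 13, "D", config)
    assert any(v[0] == "BsaI" for v in err.value.violations)


def test_swapped_oligos_fail_assembly(kit, config):
    duplex = gb.domesticate_target("G" + "ATC" * 6 + "A", "D", config)
    swapped = gb.OligoDuplex(
        fwd_oligo=duplex.rev_oligo,
        rev_oligo=duplex.fwd_oligo,
        left_fusion=duplex.left_fusion,
        right_fusion=duplex.right_fusion,
        protospacer=duplex.protospacer,
    )
    with pytest.raises(gb.AssemblyError):
        gb.assemble_grna_cassette(
            kit["parts"]["polIII_promoter"], swapped,
            kit["parts"]["scaffold_D"], kit["alpha1"], config,
        )


def test_design_round_trip_lossless(kit, config):
    """domesticate -> anneal -> assemble -> re-extract the exact 20-mer."""
    proto = "G" + "TGCA" * 4 + "CAT"
    duplex = gb.domesticate_target(proto, "D", config)
    tu = gb.assemble_grna_cassette(
        kit["parts"]["polIII_promoter"], duplex,
        kit["parts"]["scaffold_D"], kit["alpha1"], config,
    )
    assert gb.extract_protospacer(tu, config, "D") == proto


# -------------------------------------------------------- polycistron


def test_polycistron_two_targets(kit, config):
    fx = kit["fx"]
    protos = ["G" + "ATC" * 6 + "A", "G" + "TCA" * 6 + "T"]
    design = gb.PolycistronDesign(
        ordered_targets=protos,
        position_parts=[gb.minus1_part(k, 2, fx, config) for k in (1, 2)],
        promoter_part=kit["parts"]["poly_promoter"],
    )
    record = gb.build_polycistron(design, kit["alpha1"], config)
    cargo = record.insert
    assert cargo.count(config.trna_seq) == 2
    # slot order preserved: protospacer positions strictly increasing
    positions = [cargo.find(p) for p in protos]
    assert all(p != -1 for p in positions) and positions == sorted(positions)
    # transcript is scar-free: tRNA + protospacer + scaffold contiguous
    assert (config.trna_seq + protos[0] + config.scaffold_seq) in cargo


def test_polycistron_three_targets_then_binary(kit, config):
    fx = kit["fx"]
    protos2 = ["G" + "ATC" * 6 + "A", "G" + "TCA" * 6 + "T"]
    protos3 = ["G" + "CAT" * 6 + "C", "G" + "GAT" * 6 + "A", "G" + "TAC" * 6 + "G"]
    poly2 = gb.build_polycistron(
        gb.PolycistronDesign(
            protos2,
            [gb.minus1_part(k, 2, fx, config) for k in (1, 2)],
            kit["parts"]["poly_promoter"],
        ),
        kit["alpha1"], config, part_id="poly2",
    )
    poly3 = gb.build_polycistron(
        gb.PolycistronDesign(
            protos3,
            [gb.minus1_part(k, 3, fx, config) for k in (1, 2, 3)],
            kit["parts"]["poly_promoter"],
        ),
        kit["alpha2"], config, part_id="poly3",
    )
    level2 = gb.binary_assemble(poly2, poly3, kit["omega1"], config)
    assert level2.klass == "omega"
    assert level2.insert.count(config.trna_seq) == 5
    assert all(p in level2.insert for p in protos2 + protos3)


def test_polycistron_rejects_single_target(kit, config):
    with pytest.raises(gb.DesignError, match="monocistronic"):
        gb.build_polycistron(
            gb.PolycistronDesign(
                ["G" * 20],
                [gb.minus1_part(1, 1, kit["fx"], config)],
                kit["parts"]["poly_promoter"],
            ),
            kit["alpha1"], config,
        )
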