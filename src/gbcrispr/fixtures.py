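"""Deterministic synthetic fixtures: mock entry/destination vectors,
standard parts and genomes with planted targets.

Nothing here downloads anything. Vector junction regions are built exactly
from the configured enzyme geometries and fusion-site tables, so every
generated vector passes the validation of the module that consumes it;
backbones and stuffers are seeded random sequence scrubbed of stray
BsaI/BsmBI motifs. Backbone lengths default to a few kb so that digest
patterns stay human-checkable.

The junction design overlaps the BsaI and BsmBI cut windows where the braid
requires the released cargo edge to coincide with the transcriptional-unit
edge; the three braid-visible fusion sites (edge-left, junction, edge-right)
are read from the config table.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .config import ToolConfig, default_config
from .design import PolycistronDesign, build_polycistron
from .digestion import digest, find_sites
from .errors import GBError, SequenceError
from .grammar import (
    LEVEL_MINUS1,
    GBPartRecord,
    VectorSpec,
    binary_assemble,
    check_domestication,
    make_level0,
)
from .molecules import CIRCULAR, LINEAR, DNAMolecule, revcomp

_FORBIDDEN = ("GGTCTC", "GAGACC", "CGTCTC", "GAGACG")


@dataclass
class FixtureConfig:
    """Knobs of the fixture generator; same seed, byte-identical output."""

    seed: int = 1
    backbone_len: int = 2600
    stuffer_len: int = 650
    gc: float = 0.45
    n_genes: int = 2
    gene_len: int = 1200
    # (gene_index, protospacer-or-None, with_diagnostic_site)
    planted_targets: list = field(default_factory=list)


def _random_seq(rng: random.Random, n: int, gc: float) -> str:
    bases = []
    for _ in range(n):
        if rng.random() < gc:
            bases.append(rng.choice("GC"))
        else:
            bases.append(rng.choice("AT"))
    return "".join(bases)


def scrub(seq: str, motifs=_FORBIDDEN) -> str:
    """Deterministically remove every occurrence of ``motifs`` (given in
    plus-strand sense; their reverse complements are implied by the list)."""
    s = list(seq)
    changed = True
    while changed:
        changed = False
        text = "".join(s)
        for motif in motifs:
            i = text.find(motif)
            if i != -1:
                mid = i + len(motif) // 2
                s[mid] = "A" if s[mid] != "A" else "C"
                changed = True
                break
    return "".join(s)


def _clean_random(rng, n, gc):
    return scrub(_random_seq(rng, n, gc))


def _junctions(klass: str, position: int, config: ToolConfig) -> tuple[str, str]:
    """Left/right cargo-junction sequences for a braid destination vector."""
    bsai = config.bsai.recognition
    bsmbi = config.bsmbi.recognition
    w = config.braid_sites["edge_left"]
    j = config.braid_sites["junction"]
    e = config.braid_sites["edge_right"]
    if klass == "alpha":
        acc, rel = bsai, bsmbi  # accepts BsaI input, releases with BsmBI
    elif klass == "omega":
        acc, rel = bsmbi, bsai
    else:
        raise SequenceError(f"not a braid class: {klass}")
    if position == 1:
        left = rel + "A" + w + "T" + revcomp(acc)
        right = acc + "T" + e + j + "A" + revcomp(rel)
    elif position == 2:
        left = rel + "A" + j + w + "T" + revcomp(acc)
        right = acc + "T" + e + "A" + revcomp(rel)
    else:
        raise SequenceError(f"braid position must be 1 or 2, got {position}")
    return left, right


def make_vector(
    klass: str,
    cfg: FixtureConfig,
    config: ToolConfig | None = None,
    position: int = 1,
    slot: int | None = None,
    n_slots: int | None = None,
    vector_id: str | None = None,
) -> VectorSpec:
    """Build a mock vector of the requested class.

    ``entry``: pUPD-like level-0 acceptor (BsmBI in, BsaI out).
    ``alpha``/``omega``: destination vectors at braid ``position`` 1 or 2.
    ``minus1_entry``: tRNA-scaffold slot plasmid (needs ``slot``/``n_slots``).
    """
    config = config or default_config()
    bsai = config.bsai.recognition
    bsmbi = config.bsmbi.recognition

    if klass == "entry":
        release, assembly = config.bsai, config.bsmbi
        expected = {"BsaI": 0, "BsmBI": 2}
        vid = vector_id or f"pUPD_{cfg.seed}"
    elif klass == "alpha":
        release, assembly = config.bsmbi, config.bsai
        expected = {"BsaI": 2, "BsmBI": 2}
        vid = vector_id or f"pDGB3{klass}{position}_{cfg.seed}"
    elif klass == "omega":
        release, assembly = config.bsai, config.bsmbi
        expected = {"BsaI": 2, "BsmBI": 2}
        vid = vector_id or f"pDGB3{klass}{position}_{cfg.seed}"
    elif klass == "minus1_entry":
        if slot is None or n_slots is None:
            raise SequenceError("minus1_entry needs slot and n_slots")
        release, assembly = config.bsai, config.bsmbi
        expected = {"BsaI": 2, "BsmBI": 2}
        vid = vector_id or f"pVD1_slot{slot}of{n_slots}_{cfg.seed}"
    else:
        raise SequenceError(f"unknown vector class {klass!r}")

    # accidental recognition sites can arise where random segments abut the
    # designed junctions; redraw deterministically until site counts are exact
    for attempt in range(50):
        rng = random.Random(
            f"{cfg.seed}:{klass}:{position}:{slot}:{n_slots}:{attempt}"
        )
        stuffer = _clean_random(rng, cfg.stuffer_len, cfg.gc)
        backbone = _clean_random(rng, cfg.backbone_len, cfg.gc)
        if klass == "entry":
            up_l, up_r = config.entry_overhangs
            region = up_l + "T" + revcomp(bsmbi) + stuffer + bsmbi + "T" + up_r
        elif klass in ("alpha", "omega"):
            left, right = _junctions(klass, position, config)
            region = left + stuffer + right
        else:
            slot_l, slot_r = config.poly_slot_fusions(slot, n_slots)
            region = (
                bsai + "A" + slot_l + config.trna_seq + "T" + revcomp(bsmbi)
                + stuffer
                + bsmbi + "T" + config.scaffold_seq + slot_r + "A" + revcomp(bsai)
            )
        mol = DNAMolecule(vid, region + backbone, CIRCULAR)
        counts = {
            name: len(find_sites(mol, config.enzyme(name)))
            for name in ("BsaI", "BsmBI")
        }
        if counts == expected:
            spec = VectorSpec(
                vector_id=vid,
                klass=klass,
                release_enzyme=release,
                assembly_enzyme=assembly,
                molecule=mol,
                stuffer_span=(
                    region.index(stuffer),
                    region.index(stuffer) + len(stuffer),
                ),
                position=position if klass in ("alpha", "omega") else None,
            )
            _validate_vector(spec, config)
            return spec
    raise GBError(f"{vid}: could not build a clean vector in 50 attempts")


def _validate_vector(spec: VectorSpec, config: ToolConfig):
    """A freshly built vector must release its stuffer cleanly."""
    sites = find_sites(spec.molecule, spec.assembly_enzyme)
    if len(sites) != 2:
        raise GBError(
            f"{spec.vector_id}: expected 2 {spec.assembly_enzyme.name} sites, "
            f"found {len(sites)}"
        )
    frags = digest(spec.molecule, spec.assembly_enzyme)
    if len(frags) != 2:
        raise GBError(f"{spec.vector_id}: digestion did not yield 2 fragments")


def minus1_part(
    slot: int, n_slots: int, cfg: FixtureConfig, config: ToolConfig | None = None
) -> GBPartRecord:
    """The level -1 tRNA-scaffold plasmid for one polycistron slot, wrapped
    as a part record (it is both a vector and a standard part)."""
    config = config or default_config()
    vec = make_vector("minus1_entry", cfg, config, slot=slot, n_slots=n_slots)
    return GBPartRecord(
        part_id=vec.vector_id,
        name=f"tRNA-scaffold slot {slot}/{n_slots}",
        level=LEVEL_MINUS1,
        syntax=[f"SLOT{slot}of{n_slots}"],
        insert="",
        backbone_id=vec.vector_id,
        molecule=vec.molecule,
    )


def _clean_insert(rng, n, gc, codes, config):
    """Random insert that stays domesticated even once flanked by its
    fusion sites (no recognition straddling a junction)."""
    left, right = config.fusion_for_span(codes)
    for _ in range(50):
        ins = _random_seq(rng, n, gc)
        flanked = scrub(left + ins + right)
        # only accept scrub outcomes that left the fusion sites untouched
        if flanked.startswith(left) and flanked.endswith(right):
            return flanked[len(left) : len(flanked) - len(right)]
    raise GBError("could not generate a junction-safe insert")


def standard_parts(
    cfg: FixtureConfig, config: ToolConfig | None = None
) -> dict[str, GBPartRecord]:
    """Level-0 fixture parts covering the guide-RNA and Cas9 workflows."""
    config = config or default_config()
    rng = random.Random(f"{cfg.seed}:parts")
    entry = make_vector("entry", cfg, config)

    def lvl0(part_id, codes, insert=None, length=180):
        if insert is None:
            insert = _clean_insert(rng, length, cfg.gc, codes, config)
        return make_level0(insert, codes, entry, config, part_id=part_id)

    return {
        "polIII_promoter": lvl0("GB_U6p", ["PROM-POLIII"]),
        "scaffold_D": lvl0("GB_scafD", ["SCAFFOLD-D"], config.scaffold_seq[4:]),
        "scaffold_M": lvl0("GB_scafM", ["SCAFFOLD-M"], config.scaffold_seq),
        "poly_promoter": lvl0("GB_U3p", ["PROM-POLY"]),
        "cas9_promoter": lvl0("GB_35Sp", ["A1"], length=250),
        "cas9_cds": lvl0("GB_hCas9", ["B3-B5"], length=900),
        "terminator": lvl0("GB_Tnos", ["B6-C1"], length=150),
    }


def _random_protospacer(rng, with_diagnostic_site: bool) -> str:
    if with_diagnostic_site:
        # SpeI recognition at protospacer offsets 14..20 straddles the
        # blunt cut at offset 17 (strictly inside the span)
        proto = "G" + _random_seq(rng, 13, 0.45) + "ACTAGT"
    else:
        proto = "G" + _random_seq(rng, 19, 0.45)
    return scrub(proto) if not with_diagnostic_site else proto


def make_genome(
    cfg: FixtureConfig, config: ToolConfig | None = None
) -> tuple[DNAMolecule, list[dict]]:
    """Linear mock genome with planted 20-nt + NGG targets and their truth
    table (gene label, protospacer, strand, coordinate, diagnostics).

    Planted protospacers start with G and are domesticated by construction;
    a collision (a planted 20-mer occurring anywhere else on either strand)
    triggers a deterministic regeneration.
    """
    if cfg.n_genes < 1:
        raise SequenceError("need n_genes >= 1")
    for attempt in range(100):
        rng = random.Random(f"{cfg.seed}:genome:{attempt}")
        n = cfg.n_genes * cfg.gene_len
        background = list(_clean_random(rng, n, cfg.gc))

        protos: list[str] = []
        for gi, given, _diag in cfg.planted_targets:
            if not (0 <= gi < cfg.n_genes):
                raise SequenceError(f"gene index {gi} out of range")
        for gi, given, diag in cfg.planted_targets:
            if given is not None:
                proto = given.upper()
                if len(proto) != 20:
                    raise SequenceError("planted protospacer must be 20 nt")
            else:
                proto = _random_protospacer(rng, diag)
            protos.append(proto)

        rows, used = [], []
        ok = True
        for (gi, _given, diag), proto in zip(cfg.planted_targets, protos):
            lo, hi = gi * cfg.gene_len, (gi + 1) * cfg.gene_len
            start = rng.randrange(lo + 20, hi - 60)
            if any(abs(start - u) < 40 for u in used):
                ok = False
                break
            used.append(start)
            pam = rng.choice("ACGT") + "GG"
            background[start : start + 23] = list(proto + pam)
            rows.append(
                {
                    "gene_id": f"gene{gi + 1}",
                    "protospacer": proto,
                    "pam": pam,
                    "strand": "+",
                    "start": start,
                    "diagnostic": ["SpeI"] if diag else [],
                }
            )
        if not ok:
            continue

        seq = "".join(background)
        # each planted 20-mer must occur exactly as often as planted
        from collections import Counter

        counts = Counter(p for p in protos)
        for proto, expect in counts.items():
            seen = _count_occurrences(seq, proto) + _count_occurrences(
                seq, revcomp(proto)
            )
            if seen != expect:
                ok = False
                break
        # auto-generated guides must stay domesticated in both cloning
        # contexts (mono- and polycistronic fusion flanks), or be redrawn
        generated = {
            p for (gi, given, d), p in zip(cfg.planted_targets, protos)
            if given is None
        }
        if ok and not all(
            _cloneable(p, config) for p in generated
        ) :
            ok = False
        if ok and all(not check_domestication(p) for p in set(protos)):
            genome = DNAMolecule(f"fixture_genome_{cfg.seed}", seq, LINEAR)
            return genome, rows
    raise GBError("could not place planted targets without collisions")


def _cloneable(proto: str, config: ToolConfig) -> bool:
    """True when the guide survives domestication with every fusion-site
    flank it may meet (D/M elements and polycistron slots)."""
    for mode in ("D", "M", "poly:1"):
        left, right = config.duplex_fusions(mode)
        if check_domestication(left + proto + right, config=config):
            return False
    return True


def _count_occurrences(hay: str, needle: str) -> int:
    count, i = 0, hay.find(needle)
    while i != -1:
        count += 1
        i = hay.find(needle, i + 1)
    return count


def multiplex_demo(seed: int = 1, config: ToolConfig | None = None) -> dict:
    """End-to-end 2-D multiplexing build on fixtures.

    Plants five protospacers across seven gene labels (one protospacer
    shared by three genes), builds a 2-target and a 3-target polycistronic
    tRNA-gRNA (level 1, alpha positions 1 and 2) and combines them into a
    single omega-hosted level-2 construct carrying all five guides.
    Returns the intermediate records, the final construct and the truth
    table.
    """
    config = config or default_config()
    # resolve the shared guide deterministically: draw gene 3's guide first,
    # then plant the same protospacer in genes 4 and 5
    probe_cfg = FixtureConfig(
        seed=seed, n_genes=7, gene_len=900,
        planted_targets=[(2, None, False)],
    )
    _, probe_rows = make_genome(probe_cfg, config)
    shared = probe_rows[0]["protospacer"]
    gcfg = FixtureConfig(
        seed=seed,
        n_genes=7,
        gene_len=900,
        planted_targets=[
            (0, None, True),   # XT1-like, diagnostic site at the cut
            (1, None, True),   # XT2-like
            (2, shared, False),  # FucT guide shared by three genes
            (3, shared, False),
            (4, shared, False),
            (5, None, False),
            (6, None, False),
        ],
    )
    genome, truth = make_genome(gcfg, config)

    vcfg = FixtureConfig(seed=seed)
    parts = standard_parts(vcfg, config)
    alpha1 = make_vector("alpha", vcfg, config, position=1)
    alpha2 = make_vector("alpha", vcfg, config, position=2)
    omega1 = make_vector("omega", vcfg, config, position=1)

    xt_protos = [truth[0]["protospacer"], truth[1]["protospacer"]]
    fuct_protos = [shared, truth[5]["protospacer"], truth[6]["protospacer"]]

    poly_xt = build_polycistron(
        PolycistronDesign(
            ordered_targets=xt_protos,
            position_parts=[minus1_part(k, 2, vcfg, config) for k in (1, 2)],
            promoter_part=parts["poly_promoter"],
        ),
        alpha1,
        config,
        part_id="polycistron_XT",
    )
    poly_fuct = build_polycistron(
        PolycistronDesign(
            ordered_targets=fuct_protos,
            position_parts=[minus1_part(k, 3, vcfg, config) for k in (1, 2, 3)],
            promoter_part=parts["poly_promoter"],
        ),
        alpha2,
        config,
        part_id="polycistron_FucT",
    )
    level2 = binary_assemble(
        poly_xt, poly_fuct, omega1, config, part_id="level2_5guides"
    )
    return {
        "genome": genome,
        "truth": truth,
        "parts": parts,
        "poly_xt": poly_xt,
        "poly_fuct": poly_fuct,
        "level2": level2,
        "protospacers": xt_protos + fuct_protos,
    }
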