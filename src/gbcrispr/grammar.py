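"""The GoldenBraid grammar: part levels, positional syntax, domestication,
entry cloning and the alpha/omega binary braid.

The standard uses two Type IIS enzymes. BsaI assembles level-0 parts
(promoter, CDS, terminator, guide-RNA target...) into transcriptional units
hosted in alpha destination vectors; BsmBI then combines pairs of units into
higher-order constructs hosted in omega vectors, whose cargo is in turn
released by BsaI — so alpha and omega alternate indefinitely (the "braid").
A part is *domesticated* when its sequence contains no internal BsaI or
BsmBI recognition on either strand; only domesticated inserts may enter the
standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import config as _cfg
from .digestion import digest, find_sites
from .errors import (
    AssemblyError,
    BraidViolationError,
    DomesticationError,
    SequenceError,
)
from .ligation import golden_gate
from .molecules import CIRCULAR, DNAMolecule, EnzymeSpec, Fragment, revcomp

LEVEL_MINUS1 = "minus1"
LEVEL0 = "level0"
LEVEL1PLUS = "level1plus"


@dataclass(frozen=True)
class SyntaxPosition:
    """A positional syntax code with its flanking 4-nt fusion sites."""

    code: str
    left_fusion: str
    right_fusion: str


@dataclass
class VectorSpec:
    """An entry or destination vector with its cloning chemistry.

    Alpha vectors accept BsaI multipartite input and release their cargo
    with BsmBI; omega vectors the converse. ``position`` (1 or 2) fixes the
    braid fusion sites of the released cargo.
    """

    vector_id: str
    klass: str  # entry | alpha | omega | minus1_entry
    release_enzyme: EnzymeSpec
    assembly_enzyme: EnzymeSpec
    molecule: DNAMolecule
    stuffer_span: tuple[int, int] | None = None
    position: int | None = None


@dataclass
class GBPartRecord:
    """A standardized part: its insert, hosting backbone and full plasmid."""

    part_id: str
    name: str
    level: str  # minus1 | level0 | level1plus
    syntax: list = field(default_factory=list)
    insert: str = ""
    backbone_id: str = ""
    molecule: DNAMolecule | None = None
    klass: str | None = None  # alpha | omega for level1plus records
    position: int | None = None


def check_domestication(seq: str, config=None) -> list[tuple[str, str, int]]:
    """List every internal BsaI/BsmBI recognition occurrence on either
    strand as ``(enzyme, strand, offset)``; empty means domesticated."""
    cfg = config
    enzymes = (
        (cfg.bsai, cfg.bsmbi) if cfg is not None else (_cfg.BSAI, _cfg.BSMBI)
    )
    seq = seq.upper()
    violations = []
    for enzyme in enzymes:
        for strand, pattern in (("+", enzyme.recognition),
                                ("-", revcomp(enzyme.recognition))):
            start = seq.find(pattern)
            while start != -1:
                violations.append((enzyme.name, strand, start))
                start = seq.find(pattern, start + 1)
    violations.sort(key=lambda v: (v[2], v[0], v[1]))
    return violations


def entry_insert_fragment(
    insert: str, left_fusion: str, right_fusion: str, config
) -> Fragment:
    """The sticky fragment cloned into a pUPD-like entry vector: the insert
    flanked by its fusion sites and inward-facing BsaI sites (for later
    release), carried on the entry vector's BsmBI overhangs."""
    up_l, up_r = config.entry_overhangs
    bsai = config.bsai.recognition
    core = (
        bsai + "A" + left_fusion + insert + right_fusion + "T" + revcomp(bsai)
    )
    return Fragment(core=core, left_overhang=up_l, right_overhang=up_r)


def make_level0(
    insert: str,
    syntax_codes: list[str],
    entry_vector: VectorSpec,
    config,
    part_id: str = "GB_part",
    name: str = "",
) -> GBPartRecord:
    """Clone a domesticated insert into an entry vector as a level-0 part.

    Simulates the BsmBI restriction-ligation of the fusion-site-flanked
    insert into the entry backbone. The stored plasmid round-trips: BsaI
    release regenerates exactly fusion sites + insert.
    """
    insert = insert.upper()
    if not insert:
        raise SequenceError("empty insert")
    if entry_vector.klass not in ("entry", "minus1_entry"):
        raise SequenceError(
            f"{entry_vector.vector_id}: not an entry vector"
        )
    left_fus, right_fus = config.fusion_for_span(syntax_codes)
    # check the fusion-flanked insert: a recognition site straddling the
    # insert/fusion junction is just as fatal as an internal one
    violations = check_domestication(left_fus + insert + right_fus, config=config)
    if violations:
        raise DomesticationError(violations)
    frag = entry_insert_fragment(insert, left_fus, right_fus, config)
    products = golden_gate(
        [], entry_vector.molecule, config.bsmbi, extra_fragments=(frag,)
    )
    hosted = [p for p in products if any(a[0] == "backbone" for a in p.annotations)]
    if len(hosted) != 1:
        raise AssemblyError(
            f"level-0 cloning of {part_id} yielded {len(hosted)} hosted products"
        )
    plasmid = hosted[0]
    plasmid.id = part_id
    released = release_insert(plasmid, config.bsai)
    expected = left_fus + insert + right_fus
    if released != expected:
        raise AssemblyError(f"level-0 round trip failed for {part_id}")
    return GBPartRecord(
        part_id=part_id,
        name=name or part_id,
        level=LEVEL0,
        syntax=list(syntax_codes),
        insert=insert,
        backbone_id=entry_vector.vector_id,
        molecule=plasmid,
    )


def release_insert(plasmid: DNAMolecule, enzyme: EnzymeSpec) -> str:
    """Top strand (incl. both overhangs) of the recognition-free fragment
    released when ``enzyme`` cuts ``plasmid`` — the part cargo."""
    frags = [f for f in digest(plasmid, enzyme) if not f.circular]
    clean = [
        f
        for f in frags
        if not find_sites(DNAMolecule("probe", f.top_strand), enzyme)
    ]
    if not clean:
        raise AssemblyError(f"{plasmid.id}: no recognition-free cargo fragment")
    # the cargo is the non-backbone fragment: pick the one NOT carrying the
    # partner enzyme's release geometry; fall back to the shorter fragment
    return min(clean, key=lambda f: len(f.core)).top_strand


def binary_assemble(
    tu_a: GBPartRecord,
    tu_b: GBPartRecord,
    destination: VectorSpec,
    config,
    part_id: str = "GB_binary",
) -> GBPartRecord:
    """Combine two same-class transcriptional units into the opposite-class
    destination — one turn of the braid.

    The inputs' hosting class fixes the enzyme: alpha cargo is released by
    BsmBI (and lands in omega), omega cargo by BsaI (landing in alpha).
    Output class alternates with the input class.
    """
    for tu in (tu_a, tu_b):
        if tu.level != LEVEL1PLUS or tu.klass not in ("alpha", "omega"):
            raise BraidViolationError(
                f"{tu.part_id}: not an alpha/omega-hosted unit"
            )
    if tu_a.klass != tu_b.klass:
        raise BraidViolationError(
            f"braid violation: inputs hosted in {tu_a.klass} and {tu_b.klass}"
        )
    if destination.klass == tu_a.klass:
        raise BraidViolationError(
            f"braid violation: {tu_a.klass} inputs need an opposite-class "
            f"destination, got {destination.klass}"
        )
    if destination.klass not in ("alpha", "omega"):
        raise BraidViolationError(
            f"{destination.vector_id}: not a braid destination"
        )
    enzyme = config.bsmbi if tu_a.klass == "alpha" else config.bsai
    products = golden_gate(
        [tu_a.molecule, tu_b.molecule], destination.molecule, enzyme
    )
    hosted = [p for p in products if any(a[0] == "backbone" for a in p.annotations)]
    if len(hosted) != 1:
        raise AssemblyError(
            f"binary assembly yielded {len(hosted)} hosted products"
        )
    plasmid = hosted[0]
    plasmid.id = part_id
    cargo = release_insert(plasmid, destination.release_enzyme)
    return GBPartRecord(
        part_id=part_id,
        name=f"{tu_a.part_id}+{tu_b.part_id}",
        level=LEVEL1PLUS,
        syntax=list(tu_a.syntax) + list(tu_b.syntax),
        insert=cargo,
        backbone_id=destination.vector_id,
        molecule=plasmid,
        klass=destination.klass,
        position=destination.position,
    )
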