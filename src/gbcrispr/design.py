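"""Guide-RNA design: target scanning, the target domesticator (protospacer
to annealed oligo duplex), cassette assembly and polycistronic multiplexing.

A target is a 20-nt protospacer followed by an NGG PAM on either strand.
SpCas9 cuts bluntly 3 bp 5' of the PAM, i.e. between protospacer positions
17 and 18 (0-based inter-nucleotide offset 17); a restriction site whose
recognition span strictly contains that offset is *diagnostic* — indels at
the cut necessarily destroy it, enabling the loss-of-site (PCR/RE) assay.

The domesticator turns a protospacer into two partially complementary
oligonucleotides whose annealed duplex carries the 4-nt fusion sites of the
chosen mode (monocistronic D/M element, or a tRNA-gRNA polycistron slot),
ready for direct use in a Type IIS restriction-ligation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .digestion import digest, find_sites
from .errors import AssemblyError, DesignError, DomesticationError, SequenceError
from .grammar import (
    LEVEL0,
    LEVEL1PLUS,
    LEVEL_MINUS1,
    GBPartRecord,
    VectorSpec,
    check_domestication,
    release_insert,
)
from .ligation import golden_gate
from .molecules import DNAMolecule, Fragment, gc_percent, revcomp

CUT_OFFSET = 17  # blunt cut between protospacer nt 17 and 18 (3 bp 5' of PAM)


@dataclass
class TargetSpec:
    """A candidate Cas9 target with its PAM context and diagnostics."""

    gene_id: str
    protospacer: str
    pam: str
    strand: str
    start: int  # leftmost plus-strand coordinate of the protospacer
    cut_offset: int = CUT_OFFSET
    diagnostic_sites: list = field(default_factory=list)  # (enzyme, rec offset)

    def __post_init__(self):
        if len(self.protospacer) != 20:
            raise DesignError(f"protospacer must be 20 nt, got {len(self.protospacer)}")
        if len(self.pam) != 3 or self.pam[1:] != "GG":
            raise DesignError(f"PAM {self.pam!r} does not match NGG")

    @property
    def gc_pct(self) -> float:
        return gc_percent(self.protospacer)

    @property
    def genome_cut(self) -> int:
        """Inter-nucleotide cut offset in plus-strand genome coordinates."""
        if self.strand == "+":
            return self.start + self.cut_offset
        return self.start + 20 - self.cut_offset


@dataclass
class OligoDuplex:
    """Two partially complementary oligos forming a sticky target element."""

    fwd_oligo: str
    rev_oligo: str
    left_fusion: str
    right_fusion: str
    protospacer: str
    substituted_5prime_g: bool = False

    def to_fragment(self) -> Fragment:
        return Fragment(
            core=self.protospacer,
            left_overhang=self.left_fusion,
            right_overhang=self.right_fusion,
        )


@dataclass
class PolycistronDesign:
    """Ordered multi-guide design for a single tRNA-gRNA transcript."""

    ordered_targets: list  # protospacer strings or TargetSpec
    position_parts: list  # level -1 tRNA-scaffold part records, one per slot
    promoter_part: GBPartRecord = None

    def protospacers(self) -> list[str]:
        return [
            t.protospacer if isinstance(t, TargetSpec) else str(t).upper()
            for t in self.ordered_targets
        ]


def anneal(fwd_oligo: str, rev_oligo: str) -> Fragment:
    """Simulate annealing of two oligos into a sticky duplex.

    Finds the unique maximal complementary register and returns the duplex
    as a fragment with plus-strand-sense overhangs. Raises when no register
    gives a double-stranded core.
    """
    fwd = fwd_oligo.upper()
    bottom = revcomp(rev_oligo.upper())  # bottom strand in plus-strand sense
    best = None
    # shift = offset of `bottom` relative to `fwd` (may be negative)
    for shift in range(-len(bottom) + 1, len(fwd)):
        lo, hi = max(0, shift), min(len(fwd), shift + len(bottom))
        if hi <= lo:
            continue
        if fwd[lo:hi] == bottom[lo - shift : hi - shift]:
            if best is None or hi - lo > best[0]:
                best = (hi - lo, shift, lo, hi)
    if best is None:
        raise DesignError("oligos do not anneal in any register")
    _, shift, lo, hi = best
    left = fwd[:lo] if lo > 0 else bottom[: -shift] if shift < 0 else ""
    right_top = fwd[hi:]
    right_bottom = bottom[hi - shift :]
    if right_top and right_bottom:
        raise DesignError("oligos leave double overhangs at one end")
    return Fragment(
        core=fwd[lo:hi],
        left_overhang=left,
        right_overhang=right_top or right_bottom,
    )


def scan_targets(
    genome: DNAMolecule,
    require_5prime_G: bool = True,
    gc_min: float | None = None,
    gc_max: float | None = None,
    require_diagnostic_site: bool = False,
    enzyme_panel: tuple = (),
    gene_id: str | None = None,
) -> list[TargetSpec]:
    """Every 20-mer + NGG on either strand of ``genome`` passing the
    filters, ordered by (coordinate, strand).

    The 5'-G requirement reflects PolIII transcription initiation; the
    diagnostic-site filter keeps only targets whose cut can be read out by
    a loss-of-site restriction assay with one of the panel enzymes.
    """
    seq = genome.sequence
    n = len(seq)
    gid = gene_id or genome.id
    hits: list[TargetSpec] = []

    def consider(proto, pam, strand, start):
        if "N" in proto or "N" in pam:
            return
        if pam[1:] != "GG":
            return
        if require_5prime_G and not proto.startswith("G"):
            return
        gc = gc_percent(proto)
        if gc_min is not None and gc < gc_min:
            return
        if gc_max is not None and gc > gc_max:
            return
        t = TargetSpec(gid, proto, pam, strand, start)
        t.diagnostic_sites = _diagnostic_sites(seq, t.genome_cut, enzyme_panel)
        if require_diagnostic_site and not t.diagnostic_sites:
            return
        hits.append(t)

    for i in range(n - 22):
        consider(seq[i : i + 20], seq[i + 20 : i + 23], "+", i)
    rc = revcomp(seq)
    for j in range(n - 22):
        consider(rc[j : j + 20], rc[j + 20 : j + 23], "-", n - j - 20)
    hits.sort(key=lambda t: (t.start, t.strand))
    return hits


def _diagnostic_sites(seq: str, cut: int, enzyme_panel) -> list[tuple[str, int]]:
    """Panel enzymes whose recognition span strictly contains ``cut``."""
    out = []
    for enzyme in enzyme_panel:
        k = enzyme.site_len
        patterns = {enzyme.recognition, revcomp(enzyme.recognition)}
        offsets = set()
        for pat in patterns:
            start = seq.find(pat, max(0, cut - k))
            while start != -1 and start < cut:
                if start < cut < start + k:
                    offsets.add(start)
                start = seq.find(pat, start + 1)
        for off in sorted(offsets):
            out.append((enzyme.name, off))
    return out


def domesticate_target(
    protospacer: str, mode: str, config, policy_5G: str | None = None
) -> OligoDuplex:
    """The target domesticator: protospacer -> annealable oligo pair.

    ``mode`` is ``"D"``/``"M"`` (monocistronic element, differing only in
    the right fusion site) or ``"poly:<k>"`` (polycistron slot k, whose
    overhangs are the tRNA 3' and scaffold 5' tetramers so the transcript
    carries no scar). ``policy_5G="substitute"`` replaces a non-G first
    base with G (and flags it); ``"reject"`` refuses it.
    """
    proto = protospacer.upper()
    if len(proto) != 20 or not set(proto) <= set("ACGT"):
        raise DesignError("protospacer must be 20 nt of A/C/G/T")
    policy = policy_5G or config.policies.get("policy_5G", "reject")
    substituted = False
    if not proto.startswith("G"):
        if policy == "substitute":
            proto = "G" + proto[1:]
            substituted = True
        else:
            raise DesignError(
                "protospacer must start with G for PolIII expression "
                "(policy_5G=reject)"
            )
    left_fus, right_fus = config.duplex_fusions(mode)
    duplex_region = left_fus + proto + right_fus
    violations = check_domestication(duplex_region, config=config)
    if violations:
        raise DomesticationError(violations)
    return OligoDuplex(
        fwd_oligo=left_fus + proto,
        rev_oligo=revcomp(proto + right_fus),
        left_fusion=left_fus,
        right_fusion=right_fus,
        protospacer=proto,
        substituted_5prime_g=substituted,
    )


def assemble_grna_cassette(
    promoter: GBPartRecord,
    duplex: OligoDuplex,
    scaffold: GBPartRecord,
    destination: VectorSpec,
    config,
    part_id: str = "gRNA_TU",
) -> GBPartRecord:
    """Single-pot BsaI assembly of promoter + target duplex + scaffold into
    an alpha destination: the complete guide-RNA expression cassette."""
    if destination.klass != "alpha":
        raise AssemblyError(
            "guide-RNA cassettes are assembled in alpha destinations"
        )
    frag = anneal(duplex.fwd_oligo, duplex.rev_oligo)  # verifies protrusions
    products = golden_gate(
        [promoter.molecule, scaffold.molecule],
        destination.molecule,
        config.bsai,
        extra_fragments=(frag,),
    )
    hosted = [p for p in products if any(a[0] == "backbone" for a in p.annotations)]
    if len(hosted) != 1:
        raise AssemblyError(f"cassette assembly yielded {len(hosted)} products")
    plasmid = hosted[0]
    plasmid.id = part_id
    cargo = release_insert(plasmid, destination.release_enzyme)
    order = promoter.insert + duplex.left_fusion + duplex.protospacer
    if order not in cargo:
        raise AssemblyError("cassette does not contain promoter+target in order")
    return GBPartRecord(
        part_id=part_id,
        name=part_id,
        level=LEVEL1PLUS,
        syntax=list(promoter.syntax) + ["TARGET"] + list(scaffold.syntax),
        insert=cargo,
        backbone_id=destination.vector_id,
        molecule=plasmid,
        klass=destination.klass,
        position=destination.position,
    )


def extract_protospacer(cassette: GBPartRecord, config, mode: str = "D") -> str:
    """Recover the exact 20-nt protospacer from an assembled cassette —
    the design round trip is lossless."""
    left_fus, right_fus = config.duplex_fusions(mode)
    seq = cassette.molecule.sequence
    doubled = seq + seq
    for hay in (doubled, revcomp(doubled)):
        i = hay.find(left_fus)
        while i != -1:
            cand = hay[i + 4 : i + 24]
            if hay[i + 24 : i + 28] == right_fus and len(cand) == 20:
                return cand
            i = hay.find(left_fus, i + 1)
    raise DesignError("no protospacer flanked by the mode's fusion sites")


def make_oligomer(
    duplex: OligoDuplex,
    position_part: GBPartRecord,
    config,
    part_id: str = "GB_oligomer",
) -> GBPartRecord:
    """BsmBI entry of a target duplex into its level -1 tRNA-scaffold
    plasmid, yielding a level-0 tRNA-gRNA oligomer."""
    if position_part.level != LEVEL_MINUS1:
        raise AssemblyError(f"{position_part.part_id}: not a level -1 part")
    frag = anneal(duplex.fwd_oligo, duplex.rev_oligo)
    products = golden_gate(
        [], position_part.molecule, config.bsmbi, extra_fragments=(frag,)
    )
    hosted = [p for p in products if any(a[0] == "backbone" for a in p.annotations)]
    if len(hosted) != 1:
        raise AssemblyError(f"oligomer cloning yielded {len(hosted)} products")
    plasmid = hosted[0]
    plasmid.id = part_id
    return GBPartRecord(
        part_id=part_id,
        name=part_id,
        level=LEVEL0,
        syntax=list(position_part.syntax),
        insert=release_insert(plasmid, config.bsai),
        backbone_id=position_part.backbone_id,
        molecule=plasmid,
    )


def build_polycistron(
    design: PolycistronDesign,
    destination: VectorSpec,
    config,
    part_id: str = "polycistron",
) -> GBPartRecord:
    """Two-stage 2-D multiplexing build.

    Stage 1: each target duplex enters its slot's level -1 tRNA-scaffold
    plasmid via BsmBI, producing a level-0 oligomer. Stage 2: BsaI
    multipartite assembly of the PolIII promoter and all n oligomers into
    an alpha destination yields the level-1 polycistronic tRNA-gRNA, with
    n tRNA units and n protospacers in slot order.
    """
    protos = design.protospacers()
    n = len(protos)
    if n < 2:
        raise DesignError(
            "a polycistron needs >= 2 targets (use the monocistronic path)"
        )
    if len(design.position_parts) != n:
        raise DesignError(
            f"{n} targets but {len(design.position_parts)} position parts"
        )
    if design.promoter_part is None:
        raise DesignError("polycistron design lacks a promoter part")

    oligomers = []
    for k, (proto, slot_part) in enumerate(zip(protos, design.position_parts), 1):
        duplex = domesticate_target(proto, f"poly:{k}", config)
        oligomers.append(
            make_oligomer(duplex, slot_part, config, part_id=f"{part_id}_olig{k}")
        )

    products = golden_gate(
        [design.promoter_part.molecule] + [o.molecule for o in oligomers],
        destination.molecule,
        config.bsai,
    )
    hosted = [p for p in products if any(a[0] == "backbone" for a in p.annotations)]
    if len(hosted) != 1:
        raise AssemblyError(f"polycistron assembly yielded {len(hosted)} products")
    plasmid = hosted[0]
    plasmid.id = part_id
    cargo = release_insert(plasmid, destination.release_enzyme)
    pos = -1
    for proto in protos:
        nxt = cargo.find(proto, pos + 1)
        if nxt == -1:
            raise AssemblyError("polycistron slot order not preserved")
        pos = nxt
    return GBPartRecord(
        part_id=part_id,
        name=part_id,
        level=LEVEL1PLUS,
        syntax=[f"SLOT{k}" for k in range(1, n + 1)],
        insert=cargo,
        backbone_id=destination.vector_id,
        molecule=plasmid,
        klass=destination.klass,
        position=destination.position,
    )
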