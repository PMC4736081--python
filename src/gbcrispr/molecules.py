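"""Sequence and topology model for the assembly simulator.

Double-stranded DNA is represented by its plus strand. A :class:`DNAMolecule`
is linear or circular; circular molecules compare equal under rotation and
reverse complement, because a plasmid has no origin. A :class:`Fragment` is a
digestion product: a double-stranded core plus the 5' single-stranded
overhangs at each end. Fragments carry no positional information, so ligation
is driven purely by overhang identity.

Coordinates are 0-based, half-open, on the plus strand; cut positions are
inter-nucleotide offsets. Circular arithmetic is modulo length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import SequenceError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")

LINEAR = "linear"
CIRCULAR = "circular"

FIVE_PRIME = "five_prime_overhang"
BLUNT = "blunt"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    """GC content of ``seq`` in percent."""
    if not seq:
        return 0.0
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def canonical_rotation(seq: str) -> str:
    """Lexicographically least rotation among ``seq`` and its reverse
    complement — the canonical form of a circular sequence."""
    best = None
    for s in (seq, revcomp(seq)):
        doubled = s + s
        for i in range(len(s)):
            rot = doubled[i : i + len(s)]
            if best is None or rot < best:
                best = rot
    return best if best is not None else ""


def canonical_linear(seq: str) -> str:
    """Canonical form of a linear duplex: the smaller of seq / revcomp."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


@dataclass
class DNAMolecule:
    """A linear or circular double-stranded DNA molecule.

    ``annotations`` is a list of ``(label, start, end, strand)`` tuples;
    features may wrap the origin only on circular molecules (expressed as
    ``end > len(sequence)``, i.e. unwrapped coordinates).
    """

    id: str
    sequence: str
    topology: str = LINEAR
    annotations: list = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise SequenceError(f"molecule {self.id!r}: empty sequence")
        if not set(self.sequence) <= VALID_BASES:
            bad = sorted(set(self.sequence) - VALID_BASES)
            raise SequenceError(f"molecule {self.id!r}: invalid bases {bad}")
        if self.topology not in (LINEAR, CIRCULAR):
            raise SequenceError(f"molecule {self.id!r}: bad topology {self.topology!r}")
        n = len(self.sequence)
        for label, start, end, strand in self.annotations:
            if start < 0 or end < start:
                raise SequenceError(f"annotation {label!r}: bad span {start}-{end}")
            limit = 2 * n if self.topology == CIRCULAR else n
            if end > limit or start >= n:
                raise SequenceError(
                    f"annotation {label!r}: span {start}-{end} outside molecule"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == CIRCULAR

    def subseq(self, start: int, end: int) -> str:
        """Plus-strand subsequence [start, end); wraps on circular molecules."""
        n = len(self.sequence)
        if self.is_circular:
            start %= n
            span = end - start if end >= start else end % n + n - start
            doubled = self.sequence + self.sequence
            return doubled[start : start + span]
        return self.sequence[start:end]

    def canonical(self) -> str:
        if self.is_circular:
            return canonical_rotation(self.sequence)
        return canonical_linear(self.sequence)

    def reverse_complement(self) -> "DNAMolecule":
        return DNAMolecule(self.id, revcomp(self.sequence), self.topology)

    def same_molecule(self, other: "DNAMolecule") -> bool:
        """Topology-aware physical identity (rotation/strand invariant)."""
        return self.topology == other.topology and self.canonical() == other.canonical()

    def __eq__(self, other):
        if not isinstance(other, DNAMolecule):
            return NotImplemented
        return self.same_molecule(other)

    def __hash__(self):
        return hash((self.topology, self.canonical()))


@dataclass(frozen=True)
class EnzymeSpec:
    """Restriction enzyme geometry.

    Type IIS enzymes (``cut_offset is None``) cut downstream of a
    non-palindromic recognition: top-strand cut ``spacer_len`` nt past the
    recognition 3' end, bottom strand ``overhang_len`` further, leaving a
    5' overhang. Ordinary within-site cutters (EcoRI, SpeI...) set
    ``cut_offset``: the top-strand cut relative to the recognition start.
    """

    name: str
    recognition: str
    spacer_len: int = 1
    overhang_len: int = 4
    cut_offset: int | None = None

    def __post_init__(self):
        if not self.recognition or not set(self.recognition) <= set("ACGT"):
            raise SequenceError(f"enzyme {self.name}: bad recognition")
        if self.spacer_len < 0 or not (0 <= self.overhang_len <= 8):
            raise SequenceError(f"enzyme {self.name}: bad geometry")

    @property
    def is_type_iis(self) -> bool:
        return self.cut_offset is None

    @property
    def site_len(self) -> int:
        return len(self.recognition)


@dataclass(frozen=True)
class SiteMatch:
    """One recognition-site occurrence with its resolved cut geometry.

    ``cut_top``/``cut_bottom`` are inter-nucleotide offsets on the plus
    strand; ``cut_bottom - cut_top == overhang_len`` for a 5' overhang.
    """

    enzyme: EnzymeSpec
    strand: str  # "+" or "-"
    rec_start: int
    cut_top: int
    cut_bottom: int


@dataclass(frozen=True)
class Fragment:
    """Position-free digestion product.

    ``core`` is the fully double-stranded region (plus strand). Overhangs
    are stored in plus-strand sense: ``left_overhang`` is the 4-mer whose
    top strand protrudes at the left end; ``right_overhang`` is the 4-mer
    whose bottom strand protrudes at the right end. Two fragments ligate
    when one's right overhang equals the other's left overhang.
    """

    core: str
    left_overhang: str = ""
    right_overhang: str = ""
    left_chemistry: str = BLUNT
    right_chemistry: str = BLUNT
    circular: bool = False  # marker for an uncut circular input

    def __post_init__(self):
        if self.left_overhang and self.left_chemistry == BLUNT:
            object.__setattr__(self, "left_chemistry", FIVE_PRIME)
        if self.right_overhang and self.right_chemistry == BLUNT:
            object.__setattr__(self, "right_chemistry", FIVE_PRIME)

    @property
    def top_strand(self) -> str:
        """Top-strand sequence including both overhang regions."""
        return self.left_overhang + self.core + self.right_overhang

    @property
    def top_length(self) -> int:
        """Length counting the left overhang once (tiles a digest exactly)."""
        return len(self.left_overhang) + len(self.core)

    def reverse_complement(self) -> "Fragment":
        return Fragment(
            core=revcomp(self.core),
            left_overhang=revcomp(self.right_overhang),
            right_overhang=revcomp(self.left_overhang),
            left_chemistry=self.right_chemistry,
            right_chemistry=self.left_chemistry,
            circular=self.circular,
        )

    def canonical(self) -> tuple:
        fwd = (self.left_overhang, self.core, self.right_overhang)
        rc = self.reverse_complement()
        rev = (rc.left_overhang, rc.core, rc.right_overhang)
        return min(fwd, rev)
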