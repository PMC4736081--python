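"""Tool configuration: enzyme geometries, fusion-site (overhang) tables,
scaffold/tRNA sequences and design policies.

Everything here is data, not logic: the grammar and design modules read
these tables and never hard-code a fusion site. Defaults can be overridden
from a YAML file via :func:`load_config`.

Default fusion sites follow the plant common-syntax convention of 4-nt
junctions chaining left-to-right through a transcriptional unit
(GGAG ... CGCT), with CRISPR-specific positions for the guide-RNA target
element and the polycistronic tRNA-gRNA slots.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import yaml

from .errors import SequenceError
from .molecules import EnzymeSpec

# --- Type IIS assembly enzymes (geometry: recognition + spacer + 5' overhang)
BSAI = EnzymeSpec("BsaI", "GGTCTC", spacer_len=1, overhang_len=4)
BSMBI = EnzymeSpec("BsmBI", "CGTCTC", spacer_len=1, overhang_len=4)

# --- ordinary within-site cutters for diagnostic digests (top cut offset
#     from recognition start; all leave 4-nt 5' overhangs)
STANDARD_ENZYMES = {
    "SpeI": EnzymeSpec("SpeI", "ACTAGT", overhang_len=4, cut_offset=1),
    "BamHI": EnzymeSpec("BamHI", "GGATCC", overhang_len=4, cut_offset=1),
    "EcoRI": EnzymeSpec("EcoRI", "GAATTC", overhang_len=4, cut_offset=1),
    "HindIII": EnzymeSpec("HindIII", "AAGCTT", overhang_len=4, cut_offset=1),
    "BsaI": BSAI,
    "BsmBI": BSMBI,
}

# Canonical SpCas9 single-guide scaffold (trans-activating segment).
SCAFFOLD_SEQ = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
)

# Pre-tRNA(Gly) used by the rice polycistronic tRNA-gRNA strategy; processed
# off the transcript by endogenous RNases P and Z.
TRNA_SEQ = (
    "AACAAAGCACCAGTGGTCTAGTGGTAGAATAGTACCCTGCCACGGTACAGACCCGGGTTCGATTCCCGGCTGGTGCA"
)

# Transcriptional-unit syntax positions: code -> (left fusion, right fusion).
# Adjacent positions chain; the TU always spans GGAG ... CGCT.
SYNTAX_TABLE = {
    # generic protein-coding TU
    "A1": ("GGAG", "AATG"),   # promoter (+5' UTR)
    "B3-B5": ("AATG", "GCTT"),  # CDS
    "B6-C1": ("GCTT", "CGCT"),  # terminator
    # guide-RNA cassette
    "PROM-POLIII": ("GGAG", "ATTG"),  # PolIII promoter, monocistronic guides
    "B3c": ("ATTG", "TAGC"),
    "B4": ("TAGC", "CGAA"),
    "B5c": ("CGAA", "GTTT"),  # D-Target right edge = scaffold 5' tetramer
    "B5d": ("CGAA", "GCTT"),  # M-Target right edge
    "SCAFFOLD-D": ("GTTT", "CGCT"),
    "SCAFFOLD-M": ("GCTT", "CGCT"),
    # polycistronic tRNA-gRNA
    "PROM-POLY": ("GGAG", "ACCA"),
}

# Fusion-site pool for polycistron slot boundaries: slot k runs from
# POLY_SLOT_SITES[k-1] to POLY_SLOT_SITES[k]; the final slot closes on CGCT.
POLY_SLOT_SITES = ["ACCA", "CAGG", "TCAG", "GTAA", "CTTC", "AGAC", "TGGA"]

# Entry-vector (pUPD-like) cloning overhangs for level-0 domestication.
ENTRY_OVERHANGS = ("CTCG", "TGAG")

# Braid fusion sites shared by the alpha/omega loop: position-1 cargo spans
# EDGE_LEFT..JUNCTION, position-2 cargo JUNCTION..EDGE_RIGHT; a destination
# backbone exposes EDGE_LEFT/EDGE_RIGHT. EDGE_* coincide with the TU span.
BRAID_SITES = {"edge_left": "GGAG", "junction": "TGCC", "edge_right": "CGCT"}


@dataclass
class ToolConfig:
    """Bundle of tables and policies consumed by the grammar/design layers."""

    enzymes: dict = field(default_factory=lambda: dict(STANDARD_ENZYMES))
    syntax_table: dict = field(default_factory=lambda: copy.deepcopy(SYNTAX_TABLE))
    poly_slot_sites: list = field(default_factory=lambda: list(POLY_SLOT_SITES))
    braid_sites: dict = field(default_factory=lambda: dict(BRAID_SITES))
    entry_overhangs: tuple = ENTRY_OVERHANGS
    scaffold_seq: str = SCAFFOLD_SEQ
    trna_seq: str = TRNA_SEQ
    promoters: dict = field(default_factory=dict)  # name -> sequence
    policies: dict = field(
        default_factory=lambda: {
            "policy_5G": "reject",
            "cycle_cap": 10,
            "product_cap": 50,
            "rounding": "half_up_1dp",
        }
    )

    def __post_init__(self):
        self.validate()

    # -- lookups ---------------------------------------------------------
    def enzyme(self, name: str) -> EnzymeSpec:
        try:
            return self.enzymes[name]
        except KeyError:
            raise SequenceError(f"unknown enzyme {name!r}") from None

    @property
    def bsai(self) -> EnzymeSpec:
        return self.enzyme("BsaI")

    @property
    def bsmbi(self) -> EnzymeSpec:
        return self.enzyme("BsmBI")

    def fusion_for_span(self, codes: list[str]) -> tuple[str, str]:
        """Left/right fusion sites of a part spanning ``codes`` (which must
        chain: right fusion of each code equals left fusion of the next)."""
        if not codes:
            raise SequenceError("empty syntax code list")
        sites = []
        for code in codes:
            if code not in self.syntax_table:
                raise SequenceError(f"unknown syntax code {code!r}")
            sites.append(self.syntax_table[code])
        for (l1, r1), (l2, r2) in zip(sites, sites[1:]):
            if r1 != l2:
                raise SequenceError(
                    f"syntax codes do not chain: {r1} != {l2} in {codes}"
                )
        return sites[0][0], sites[-1][1]

    def poly_slot_fusions(self, slot: int, n_slots: int) -> tuple[str, str]:
        """Fusion sites flanking polycistron slot ``slot`` (1-based) of
        ``n_slots``; the last slot closes the chain on the TU right edge."""
        if not (1 <= slot <= n_slots):
            raise SequenceError(f"slot {slot} outside 1..{n_slots}")
        if n_slots > len(self.poly_slot_sites):
            raise SequenceError(
                f"{n_slots} slots exceed the configured site pool "
                f"({len(self.poly_slot_sites)})"
            )
        left = self.poly_slot_sites[slot - 1]
        right = (
            self.braid_sites["edge_right"]
            if slot == n_slots
            else self.poly_slot_sites[slot]
        )
        return left, right

    def duplex_fusions(self, mode: str) -> tuple[str, str]:
        """Overhangs of the annealed target duplex for a design mode:
        'D'/'M' monocistronic elements, or 'poly:<k>' for a polycistron slot
        (the tRNA 3' and scaffold 5' tetramers — a scar-free junction)."""
        if mode == "D":
            return self.fusion_for_span(["B3c", "B4", "B5c"])
        if mode == "M":
            return self.fusion_for_span(["B3c", "B4", "B5d"])
        if mode.startswith("poly:"):
            int(mode.split(":", 1)[1])  # validates slot number
            return self.trna_seq[-4:], self.scaffold_seq[:4]
        raise SequenceError(f"unknown design mode {mode!r}")

    # -- validation ------------------------------------------------------
    def validate(self):
        for code, (lf, rf) in self.syntax_table.items():
            for site in (lf, rf):
                if len(site) != 4 or not set(site) <= set("ACGT"):
                    raise SequenceError(f"syntax {code}: bad fusion site {site!r}")
        if len(set(self.poly_slot_sites)) != len(self.poly_slot_sites):
            raise SequenceError("polycistron slot sites not unique")
        for name, seq in (("scaffold", self.scaffold_seq), ("tRNA", self.trna_seq)):
            from .grammar import check_domestication  # local import: no cycle at load

            if check_domestication(seq, config=self):
                raise SequenceError(f"{name} sequence is not domesticated")


def default_config() -> ToolConfig:
    return ToolConfig()


def load_config(path) -> ToolConfig:
    """Load a YAML override file; unspecified keys keep package defaults.

    Recognized top-level keys: ``enzymes`` (list of {name, recognition,
    spacer_len, overhang_len, cut_offset}), ``syntax_table``,
    ``poly_slot_sites``, ``braid_sites``, ``scaffold_seq``, ``trna_seq``,
    ``promoters``, ``policies``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = ToolConfig()
    if "enzymes" in raw:
        for ez in raw["enzymes"]:
            spec = EnzymeSpec(
                ez["name"],
                ez["recognition"],
                spacer_len=ez.get("spacer_len", 1),
                overhang_len=ez.get("overhang_len", 4),
                cut_offset=ez.get("cut_offset"),
            )
            cfg.enzymes[spec.name] = spec
    for key in ("scaffold_seq", "trna_seq"):
        if key in raw:
            setattr(cfg, key, raw[key].upper())
    if "syntax_table" in raw:
        for code, pair in raw["syntax_table"].items():
            cfg.syntax_table[code] = (pair[0].upper(), pair[1].upper())
    if "poly_slot_sites" in raw:
        cfg.poly_slot_sites = [s.upper() for s in raw["poly_slot_sites"]]
    if "braid_sites" in raw:
        cfg.braid_sites.update(
            {k: v.upper() for k, v in raw["braid_sites"].items()}
        )
    if "promoters" in raw:
        cfg.promoters.update({k: v.upper() for k, v in raw["promoters"].items()})
    if "policies" in raw:
        cfg.policies.update(raw["policies"])
    cfg.validate()
    return cfg
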