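"""Sticky-end ligation and Golden Gate (one-pot digestion-ligation) assembly.

Ligation builds a directed compatibility graph over fragments in both
orientations (edge when a right overhang equals another fragment's left
overhang, both read in plus-strand sense) and enumerates the distinct simple
cycles — circular ligation products — with each physical fragment used at
most once per product. The Golden Gate endpoint is modelled by keeping only
circular products that have lost every recognition site of the assembly
enzyme: in the cyclic reaction those are the only species the enzyme can no
longer re-open.
"""

from __future__ import annotations

import warnings
from collections import Counter

from .digestion import digest, find_sites
from .errors import AssemblyError, LigationCapError
from .molecules import CIRCULAR, LINEAR, DNAMolecule, EnzymeSpec, Fragment, revcomp

DEFAULT_CYCLE_CAP = 10  # max fragments per circular product
DEFAULT_PRODUCT_CAP = 50
_SEARCH_CAP = 500_000  # DFS state guard


def _oriented(fragments: list[Fragment]) -> list[list[Fragment]]:
    """Both orientations of each fragment (one if palindromic overall)."""
    out = []
    for f in fragments:
        rc = f.reverse_complement()
        opts = [f]
        if rc.top_strand != f.top_strand or rc.left_overhang != f.left_overhang:
            opts.append(rc)
        out.append(opts)
    return out


def _warn_palindromic(fragments):
    for f in fragments:
        for oh in (f.left_overhang, f.right_overhang):
            if oh and oh == revcomp(oh):
                warnings.warn(
                    f"palindromic overhang {oh}: self-ligation risk", stacklevel=3
                )


def ligate(
    fragments: list[Fragment],
    require_circular: bool = True,
    cycle_cap: int = DEFAULT_CYCLE_CAP,
    product_cap: int = DEFAULT_PRODUCT_CAP,
) -> list[DNAMolecule]:
    """Enumerate ligation products of a fragment pool.

    Circular products are reported once under rotation and strand flip, in
    lexicographic order of their canonical rotation. With
    ``require_circular=False`` maximal linear paths are reported as well.
    Uncut circular markers (from digesting a site-less plasmid) pass through
    unchanged. Blunt ends do not join.
    """
    if not fragments:
        raise AssemblyError("ligate: empty fragment list")
    passthrough = [f for f in fragments if f.circular]
    sticky = [f for f in fragments if not f.circular]
    _warn_palindromic(sticky)

    products: dict[str, DNAMolecule] = {}
    for i, f in enumerate(passthrough):
        mol = DNAMolecule(f"uncut_{i}", f.core, CIRCULAR)
        products[mol.canonical()] = mol

    options = _oriented(sticky)
    n = len(options)
    budget = [_SEARCH_CAP]

    def close_cycle(path):
        seq = "".join(fr.left_overhang + fr.core for _, fr in path)
        mol = DNAMolecule(f"cycle_{len(products)}", seq, CIRCULAR)
        products.setdefault(mol.canonical(), mol)

    def extend(path, used, start_frag):
        if budget[0] <= 0:
            raise LigationCapError(
                "ligation search exploded; raise cycle_cap/product_cap limits"
            )
        budget[0] -= 1
        last = path[-1][1]
        if not last.right_overhang:
            return
        if last.right_overhang == start_frag.left_overhang and start_frag.left_overhang:
            close_cycle(path)
        if len(path) >= cycle_cap:
            return
        start_idx = path[0][0]
        for j in range(start_idx + 1, n):
            if j in used:
                continue
            for fr in options[j]:
                if fr.left_overhang and fr.left_overhang == last.right_overhang:
                    extend(path + [(j, fr)], used | {j}, start_frag)

    for i in range(n):
        for fr in options[i]:
            if not fr.left_overhang:
                continue
            extend([(i, fr)], {i}, fr)

    if len(products) > product_cap:
        raise LigationCapError(
            f"{len(products)} circular products exceed cap {product_cap}; "
            "raise product_cap if this is intended"
        )

    out = [products[k] for k in sorted(products)]
    for i, mol in enumerate(out):
        mol.id = f"ligation_product_{i}"

    if not require_circular:
        out.extend(_maximal_linear_paths(options, budget))
    return out


def _maximal_linear_paths(options, budget) -> list[DNAMolecule]:
    n = len(options)
    found: dict[str, str] = {}

    def left_extensible(first: Fragment, used) -> bool:
        if not first.left_overhang:
            return False
        return any(
            fr.right_overhang == first.left_overhang
            for j in range(n)
            if j not in used
            for fr in options[j]
        )

    def walk(path, used):
        if budget[0] <= 0:
            raise LigationCapError("ligation search exploded")
        budget[0] -= 1
        last = path[-1][1]
        extended = False
        if last.right_overhang:
            for j in range(n):
                if j in used:
                    continue
                for fr in options[j]:
                    if fr.left_overhang == last.right_overhang and fr.left_overhang:
                        extended = True
                        walk(path + [(j, fr)], used | {j})
        if not extended and not left_extensible(path[0][1], used):
            frs = [fr for _, fr in path]
            seq = frs[0].left_overhang + "".join(
                fr.core + fr.right_overhang for fr in frs
            )
            # a path and its reverse complement are the same duplex
            key = min(seq, revcomp(seq))
            found.setdefault(key, seq)

    for i in range(n):
        for fr in options[i]:
            walk([(i, fr)], {i})

    return [
        DNAMolecule(f"linear_product_{i}", found[k], LINEAR)
        for i, k in enumerate(sorted(found))
    ]


def _backbone_fragment(destination: DNAMolecule, enzyme: EnzymeSpec) -> Fragment:
    """The destination fragment free of assembly-enzyme recognition —
    the vector backbone that survives into the product."""
    frags = digest(destination, enzyme)
    clean = []
    for f in frags:
        if f.circular:
            continue
        probe = DNAMolecule("probe", f.top_strand, LINEAR)
        if not find_sites(probe, enzyme):
            clean.append(f)
    if not clean:
        raise AssemblyError(
            f"destination {destination.id}: no recognition-free backbone fragment"
        )
    return max(clean, key=lambda f: len(f.core))


def _unmatched_overhangs(fragments: list[Fragment]) -> list[str]:
    lefts = Counter()
    rights = Counter()
    for f in fragments:
        for fr in (f, f.reverse_complement()):
            if fr.left_overhang:
                lefts[fr.left_overhang] += 1
            if fr.right_overhang:
                rights[fr.right_overhang] += 1
    unmatched = sorted(
        set(oh for oh in rights if oh not in lefts)
        | set(oh for oh in lefts if oh not in rights)
    )
    return unmatched


def golden_gate(
    parts: list[DNAMolecule],
    destination: DNAMolecule,
    enzyme: EnzymeSpec,
    extra_fragments: tuple[Fragment, ...] = (),
    cycle_cap: int = DEFAULT_CYCLE_CAP,
    product_cap: int = DEFAULT_PRODUCT_CAP,
) -> list[DNAMolecule]:
    """One-pot Type IIS assembly of ``parts`` (plasmids) and pre-annealed
    ``extra_fragments`` (oligo duplexes) into ``destination``.

    Returns the stable circular products — those with zero recognition
    sites of ``enzyme`` on either strand. The product containing the
    destination backbone is annotated ``("backbone", ...)`` and sorted
    first. Raises :class:`AssemblyError` when nothing stable closes,
    listing overhangs that found no partner.
    """
    dest_sites = find_sites(destination, enzyme)
    if len(dest_sites) < 2:
        raise AssemblyError(
            f"destination {destination.id} has {len(dest_sites)} "
            f"{enzyme.name} site(s); need >= 2 to release a stuffer"
        )
    backbone = _backbone_fragment(destination, enzyme)

    pool: list[Fragment] = list(extra_fragments)
    for mol in [*parts, destination]:
        for f in digest(mol, enzyme):
            if not f.circular:
                pool.append(f)

    candidates = ligate(pool, require_circular=True, cycle_cap=cycle_cap,
                        product_cap=product_cap)
    stable = [p for p in candidates if not find_sites(p, enzyme)]
    if not stable:
        raise AssemblyError(
            "assembly failure: no stable circular product",
            unmatched_overhangs=_unmatched_overhangs(pool),
        )

    probe = backbone.core
    flagged, rest = [], []
    for p in stable:
        doubled = p.sequence + p.sequence
        if probe in doubled or revcomp(probe) in doubled:
            p.annotations.append(("backbone", 0, len(p), "+"))
            flagged.append(p)
        else:
            rest.append(p)
    ordered = flagged + rest
    for i, p in enumerate(ordered):
        p.id = f"assembly_{i}"
    return ordered
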