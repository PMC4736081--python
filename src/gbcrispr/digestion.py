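"""Restriction-site scanning and digestion into sticky-ended fragments."""

from __future__ import annotations

from .errors import AmbiguousDigestError
from .molecules import (
    BLUNT,
    CIRCULAR,
    DNAMolecule,
    EnzymeSpec,
    Fragment,
    SiteMatch,
    revcomp,
)


def _occurrences(haystack: str, needle: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def find_sites(mol: DNAMolecule, enzyme: EnzymeSpec) -> list[SiteMatch]:
    """Every recognition occurrence on both strands, with cut geometry.

    On circular molecules sites spanning the origin are found and their cut
    offsets reduced modulo length. On linear molecules sites whose cut
    window would fall off the end are skipped (the enzyme cannot cut).
    Results are sorted by (rec_start, strand).
    """
    seq = mol.sequence
    n = len(seq)
    rec = enzyme.recognition
    k = enzyme.site_len
    if mol.is_circular and n >= k:
        scan = seq + seq[: k - 1]
    else:
        scan = seq

    matches = []
    for strand, pattern in (("+", rec), ("-", revcomp(rec))):
        for r in _occurrences(scan, pattern):
            if mol.is_circular and r >= n:
                continue
            if enzyme.cut_offset is not None:
                if strand == "+":
                    ct = r + enzyme.cut_offset
                else:
                    ct = r + k - enzyme.cut_offset - enzyme.overhang_len
            else:
                if strand == "+":
                    ct = r + k + enzyme.spacer_len
                else:
                    ct = r - enzyme.spacer_len - enzyme.overhang_len
            cb = ct + enzyme.overhang_len
            if mol.is_circular:
                ct %= n
                cb = ct + enzyme.overhang_len
            elif ct < 0 or cb > n:
                continue  # cut window off the molecule end
            matches.append(SiteMatch(enzyme, strand, r, ct, cb))

    seen = set()
    unique = []
    for m in sorted(matches, key=lambda m: (m.rec_start, m.strand)):
        key = (m.strand, m.rec_start)
        if key not in seen:
            seen.add(key)
            unique.append(m)
    return unique


def _cut_windows(mol: DNAMolecule, sites: list[SiteMatch]) -> list[tuple[int, int]]:
    """Distinct (cut_top, cut_bottom) windows, sorted; raises on overlap."""
    n = len(mol)
    windows = sorted({(s.cut_top, s.cut_bottom) for s in sites})
    for (a1, b1), (a2, b2) in zip(windows, windows[1:]):
        if a2 < b1:
            raise AmbiguousDigestError([(a1, b1), (a2, b2)])
    if mol.is_circular and len(windows) > 1:
        a_first, _ = windows[0]
        _, b_last = windows[-1]
        if a_first + n < b_last:
            raise AmbiguousDigestError([windows[-1], windows[0]])
    return windows


def digest(mol: DNAMolecule, enzyme: EnzymeSpec) -> list[Fragment]:
    """Cut ``mol`` at every site of ``enzyme``.

    A circular molecule with k >= 1 sites yields k fragments; linear with
    k sites yields k+1 fragments with blunt outer ends. An uncut circular
    molecule returns a single fragment flagged ``circular`` so callers can
    pass it through (e.g. band prediction reports it as uncut).
    """
    sites = find_sites(mol, enzyme)
    if not sites:
        if mol.is_circular:
            return [Fragment(core=mol.sequence, circular=True)]
        return [Fragment(core=mol.sequence)]

    windows = _cut_windows(mol, sites)
    frags = []
    if mol.is_circular:
        n = len(mol)
        for (ct, cb), (nt, nb) in zip(windows, windows[1:] + windows[:1]):
            core_end = nt if (nt > cb or len(windows) > 1) else ct + n
            frags.append(
                Fragment(
                    core=mol.subseq(cb, core_end),
                    left_overhang=mol.subseq(ct, cb),
                    right_overhang=mol.subseq(nt, nb),
                )
            )
    else:
        seq = mol.sequence
        first_ct, first_cb = windows[0]
        frags.append(
            Fragment(
                core=seq[:first_ct],
                right_overhang=seq[first_ct:first_cb],
                left_chemistry=BLUNT,
            )
        )
        for (ct, cb), (nt, nb) in zip(windows, windows[1:]):
            frags.append(
                Fragment(
                    core=seq[cb:nt],
                    left_overhang=seq[ct:cb],
                    right_overhang=seq[nt:nb],
                )
            )
        last_ct, last_cb = windows[-1]
        frags.append(
            Fragment(
                core=seq[last_cb:],
                left_overhang=seq[last_ct:last_cb],
                right_chemistry=BLUNT,
            )
        )
    return frags
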