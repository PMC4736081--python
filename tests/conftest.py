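"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by exhaustive enumeration
(all orderings/orientations, all k-mer positions) and never call the code
paths they check.
"""

import random
from itertools import permutations, product

import pytest

import gbcrispr as gb
from gbcrispr.molecules import canonical_rotation


@pytest.fixture(scope="session")
def config():
    return gb.default_config()


@pytest.fixture(scope="session")
def kit(config):
    """One fixture kit shared across tests: parts + destination vectors."""
    fx = gb.FixtureConfig(seed=1)
    return {
        "fx": fx,
        "parts": gb.standard_parts(fx, config),
        "entry": gb.make_vector("entry", fx, config),
        "alpha1": gb.make_vector("alpha", fx, config, position=1),
        "alpha2": gb.make_vector("alpha", fx, config, position=2),
        "omega1": gb.make_vector("omega", fx, config, position=1),
        "omega2": gb.make_vector("omega", fx, config, position=2),
    }


@pytest.fixture(autouse=True)
def _quiet_palindrome_warnings():
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="palindromic overhang")
        yield


# ---------------------------------------------------------------- oracles


def brute_force_cycles(fragments):
    """All distinct circular ligation products by exhaustive enumeration of
    fragment subsets, orderings and orientations."""
    n = len(fragments)
    results = set()
    for r in range(1, n + 1):
        for idx in permutations(range(n), r):
            if idx[0] != min(idx):
                continue  # one rotation per cyclic ordering
            for orients in product((0, 1), repeat=r):
                frs = [
                    fragments[i] if o == 0 else fragments[i].reverse_complement()
                    for i, o in zip(idx, orients)
                ]
                closed = all(
                    frs[k].right_overhang
                    and frs[k].right_overhang == frs[(k + 1) % r].left_overhang
                    for k in range(r)
                )
                if closed:
                    seq = "".join(f.left_overhang + f.core for f in frs)
                    results.add(canonical_rotation(seq))
    return results


def brute_force_scan(seq, require_5prime_G=True):
    """All 20-mer + NGG targets on both strands by position-wise checking."""
    hits = set()
    rc = gb.revcomp(seq)
    n = len(seq)
    for s, strand in ((seq, "+"), (rc, "-")):
        for i in range(n - 22):
            proto, pam = s[i : i + 20], s[i + 20 : i + 23]
            if "N" in proto or "N" in pam or pam[1] != "G" or pam[2] != "G":
                continue
            if require_5prime_G and proto[0] != "G":
                continue
            start = i if strand == "+" else n - i - 20
            hits.add((proto, pam, strand, start))
    return hits


def random_fragments(rng, n, overhang_pool):
    """A random sticky-fragment pool with overhangs from a small pool so
    that cycles exist but stay enumerable."""
    frags = []
    for _ in range(n):
        left = rng.choice(overhang_pool)
        right = rng.choice(overhang_pool)
        core = "".join(rng.choice("ACGT") for _ in range(rng.randrange(8, 30)))
        frags.append(gb.Fragment(core=core, left_overhang=left, right_overhang=right))
    return frags


def random_circular_with_sites(rng, enzyme, min_sites=1):
    """Random circular molecule guaranteed to carry >= min_sites enzyme
    sites with non-overlapping cut windows."""
    n_sites = rng.randrange(min_sites, min_sites + 3)
    chunks = []
    for _ in range(n_sites):
        filler = "".join(rng.choice("ACGT") for _ in range(rng.randrange(40, 120)))
        filler = gb.fixtures.scrub(filler)
        chunks.append(enzyme.recognition + "A" + filler)
    return gb.DNAMolecule(f"rand{rng.random()}", "".join(chunks), gb.CIRCULAR)
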