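# Methods

This note documents the models behind `gbcrispr`: what is simulated, the
choices made where the cloning standard leaves freedom, and what the tests
do and do not establish.

## Sequence and cut model

DNA is represented by its plus strand; coordinates are 0-based, half-open,
with circular arithmetic modulo length and cuts addressed as
inter-nucleotide offsets. Two circular molecules are the same plasmid iff
one sequence is a rotation of the other or of its reverse complement;
equality, hashing and product deduplication all go through that canonical
rotation.

An enzyme is a geometry, not a name: recognition sequence, spacer length
and 5′-overhang length for Type IIS cutters (BsaI `GGTCTC(N1)`, BsmBI
`CGTCTC(N1)`, both 4-nt overhangs — the commercial geometries, since the
standard never restates them), or a within-site cut offset for ordinary
palindromic enzymes used in diagnostics (SpeI `A^CTAGT`, BamHI `G^GATCC`,
EcoRI `G^AATTC`, HindIII `A^AGCTT`). On a plus-strand site the top cut is
`rec_start + |rec| + spacer`; on a minus-strand site it mirrors to
`rec_start − spacer − overhang`. Sites whose cut window would fall off a
linear molecule are reported as uncuttable; windows that overlap raise an
"ambiguous digest" error rather than guessing an order.

Fragments are position-free: a double-stranded core plus the two 4-nt
overhangs, both stored in plus-strand sense, so that ligation is a pure
string match (right overhang of one fragment = left overhang of the next).
Blunt ends never join — the simulated reactions are sticky-end only, which
is what the one-pot Type IIS chemistry selects for. Palindromic overhangs
are permitted but emit a warning (self-ligation risk); the default
tRNA 3′ tetramer `TGCA` is such a case and behaves correctly because no
competing partner exists in the reactions that use it.

## Ligation and the Golden Gate endpoint

Circular products are enumerated by a depth-first search over the overhang
compatibility graph with each physical fragment used at most once and in
one orientation per product; cycles are deduplicated under rotation and
strand flip and reported in lexicographic canonical order. Caps (10
fragments per cycle, 50 products, overridable) turn combinatorial
explosions into explicit errors. An exhaustive
ordering/orientation/subset oracle in the test suite checks the search
exactly for pools of ≤ 6 fragments.

The cyclic digestion–ligation endpoint is modelled as a filter, not a
kinetic simulation: a product is *stable* iff it contains zero recognition
sites of the assembly enzyme on either strand, because any other circle is
eventually re-opened. The simulator reports **all** stable cycles — if an
unintended multi-insert concatemer is chemically possible it appears in
the output rather than being silently filtered, since the standard gives
no grounds to guess which species dominates. Assemblies that close no
stable circle raise an error listing the overhangs that found no partner.

## The braid

The fusion-site tables ship as editable configuration; the standard's
published material does not print the 4-nt sequences, so the defaults are
the package's own coherent scheme:

* A transcriptional unit always spans `GGAG … CGCT`.
* Three braid-visible sites — edge-left `GGAG`, junction `TGCC`, edge-right
  `CGCT` — define cargo released from position-1 vectors (`GGAG…TGCC`) and
  position-2 vectors (`TGCC…CGCT`), and what a destination backbone exposes
  (`GGAG`/`CGCT`).
* At the vector junctions the BsaI and BsmBI cut windows deliberately
  overlap so the released cargo edge coincides with the unit edge where the
  braid needs it to; the recognition sites always segregate with the
  stuffer, which is why assembled products lose the assembly enzyme's sites
  but keep the partner enzyme's sites for the next release.

Consequences: α vectors accept BsaI multipartite input and release cargo
with BsmBI; Ω vectors the converse; binary products alternate class with
every round and are immediately reusable (tested to depth 4). Multipartite
assembly of level-0 parts goes into α only — level-0 cargo is BsaI-released
while Ω assembles with BsmBI, so a direct part→Ω reaction is chemically
impossible in this model (matching the protocols the standard describes,
which assemble units in α). A unit reaches Ω through a binary step.

Entry cloning (pUPD-like) uses fixed BsmBI overhangs `CTCG`/`TGAG`; the
cloned cassette carries its own inward-facing BsaI sites so that release
regenerates exactly fusion-sites + insert (round-tripped in tests).
Domestication is checked on the *fusion-flanked* insert: a recognition
site straddling the insert/fusion junction is as fatal as an internal one.

## Guide design

SpCas9 cuts bluntly 3 bp 5′ of the NGG PAM, i.e. between protospacer
positions 17 and 18 (0-based offset 17). A diagnostic site is an enzyme
whose recognition span *strictly* contains that offset — indels at the cut
then necessarily destroy the site, which is what makes the loss-of-site
PCR/RE assay work. Sites merely touching the cut boundary do not qualify.
GC filtering is off by default (bounds inclusive when enabled); the GC
content of a guide is annotated, not enforced, because it is descriptive
in the source material.

The domesticator emits full-length complementary oligos with 4-nt 5′
protrusions (no phosphorylation modelling). Monocistronic D- and M-elements
differ only in the right fusion site — both syntaxes are configuration
entries, as the distinction is asserted but not defined in the source.
Polycistronic slots use the tRNA 3′ tetramer and scaffold 5′ tetramer as
overhangs, so the assembled transcript is scar-free:
`tRNA + protospacer + scaffold` exactly, per slot. A non-G first base is
rejected by default (`policy_5G="reject"`) or substituted and flagged.

Default RNA sequences are the canonical SpCas9 single-guide scaffold
(76 nt) and the pre-tRNA-Gly of the rice polycistronic strategy (77 nt);
both pass domestication and are configuration entries. Level −1
tRNA–scaffold plasmids are slot-specific (the slot fixes the flanking
fusion sites, drawn from a pool of seven distinct 4-mers, the last slot
closing on `CGCT`), mirroring the position-specific plasmid set the
standard distributes.

## Assay arithmetic

* `corrected_mutation_rate(raw%, wt_frac) = raw% × (1 − wt_frac)`, rounded
  to one decimal, **half up** — the rounding convention is chosen so the
  published example values (17 %, 0.29 → 12.1 %; 14.5 %, 0.32 → 9.9 %)
  reproduce exactly; banker's rounding would not. Raw resistant fractions
  are user inputs: gel densitometry is out of scope.
* Band prediction counts distinct cut positions; k cuts on a circle give
  k bands summing to the length, k cuts on a linear molecule k+1 bands; an
  uncut circle is reported as such (no band list).
* Reporter normalization divides every Fluc/Rluc ratio by the reference
  condition's mean ratio, making the reference exactly 1 by construction;
  per-condition SD is the sample SD (n−1) of normalized ratios, and the
  induction range is max/min of non-reference means. The statistic is
  scale-invariant in Fluc by construction. No hypothesis testing is done —
  the source reports only mean ± SD.

## Synthetic fixtures: what they do and do not establish

The generator emulates the *combinatorial* structure of the cloning
system: vectors with correctly oriented release/acceptance sites,
domesticated parts of realistic sizes (backbones a few kb so digest
patterns stay human-checkable), genomes with planted, filter-satisfying
targets recorded in a truth table. Backgrounds are uniform random with
configurable GC; accidental enzyme sites at segment boundaries are
removed by deterministic redraw, and planted guides are redrawn if they
collide with the background or would fail domestication in any cloning
context. Same seed, byte-identical output.

A green test therefore establishes that the *logic* of scanning,
domestication, assembly and the braid is correct and self-consistent. It
does not establish anything about wet-lab efficiencies: transformation
counts, editing rates per guide, reporter magnitudes and gel intensities
are experimental quantities the simulator deliberately does not predict
(the published 11 % single-guide efficiency, derived from band
densitometry, is documented but not a computable target). Real plant
genomes (repeats, introns, paralogues) are also not emulated; off-target
scoring is delegated to external designers.

## Numerical and degenerate-input choices

Half-up decimal rounding via exact decimal arithmetic (no binary float
round-trip); rotation canonicalization by direct minimum over rotations
(molecules are desk-scale, so O(n²) is irrelevant); deterministic
tie-breaks everywhere (site lists by coordinate then strand, products by
canonical sequence); empty fragment pools, missing reference conditions,
zero-site digests and single-target polycistrons all raise typed errors
rather than returning partial results. Workflow specs are validated
step-by-step and failures carry the step id (assembly errors additionally
list unmatched overhangs).
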