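"""Scan a mock genome for Cas9 targets the way the toolbox selects them:
20-mers followed by NGG, starting with G (PolIII initiation), optionally
with a diagnostic restriction site overlapping the cut for later mutation
detection."""

import gbcrispr as gb

config = gb.default_config()

# two-gene fixture genome with one planted target per gene; the first
# carries a SpeI site straddling the Cas9 cut
fx = gb.FixtureConfig(
    seed=4, n_genes=2, gene_len=1500,
    planted_targets=[(0, None, True), (1, None, False)],
)
genome, truth = gb.make_genome(fx, config)
print(f"genome: {genome.id}, {len(genome)} bp, {fx.n_genes} gene regions")

spe = config.enzyme("SpeI")
hits = gb.scan_targets(genome, require_5prime_G=True, enzyme_panel=[spe])
print(f"candidate targets (G + 20-mer + NGG, both strands): {len(hits)}")

diagnostic = [t for t in hits if t.diagnostic_sites]
print(f"with a SpeI site overlapping the cut: {len(diagnostic)}")
for t in diagnostic[:3]:
    print(
        f"  {t.strand}{t.start:>6}  {t.protospacer}  PAM {t.pam} "
        f"GC {t.gc_pct:.0f}%  diagnostics {t.diagnostic_sites}"
    )

planted = {r["protospacer"] for r in truth}
recovered = planted & {t.protospacer for t in hits}
print(f"planted guides recovered by the scan: {len(recovered)}/{len(planted)}")
# A diagnostic target lets a later PCR/RE assay read out editing as loss of
# the restriction site; non-diagnostic targets need sequencing instead.
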