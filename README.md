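# gbcrispr

A desk-scale designer and simulator for building CRISPR/Cas9 constructs in
the GoldenBraid (GB) modular cloning standard, aimed at plant synthetic
biologists who assemble guide-RNA and Cas9 transcriptional units into binary
T-DNA vectors.

The package models the chemistry the standard is built on — Type IIS
restriction enzymes (BsaI, BsmBI) that cut outside their recognition sites
and leave programmable 4-nt 5′ overhangs ("fusion sites") — and everything
the standard layers on top:

* **Assembly simulation** (`digestion`, `ligation`): site scanning with full
  cut geometry, digestion of linear/circular molecules into sticky-ended
  fragments, enumeration of circular ligation products over the overhang
  compatibility graph, and the Golden Gate endpoint (only products that have
  lost every assembly-enzyme site are stable in a cyclic
  digestion–ligation reaction).
* **The GB grammar** (`grammar`): part levels (−1/0/1+), positional syntax
  codes with a configurable fusion-site table, domestication checks
  (no internal BsaI/BsmBI on either strand), entry-vector cloning, and the
  α/Ω *braid* — two α-hosted transcriptional units combine into an Ω vector
  and vice versa, so constructs grow indefinitely while alternating class.
* **Guide design** (`design`): genome scanning for 20-nt protospacers with
  NGG PAM (5′-G required for PolIII expression; optional diagnostic
  restriction site overlapping the Cas9 cut 3 bp from the PAM), the target
  *domesticator* that turns a protospacer into two annealable oligos with
  the right overhangs, monocistronic cassette assembly
  (promoter + target + scaffold), and polycistronic tRNA–gRNA multiplexing
  built from level −1 tRNA–scaffold slot plasmids.
* **Assay arithmetic** (`assay`): restriction band prediction for clone
  screening, PCR/RE loss-of-site assay design, the corrected mutation rate

      rate% = raw_resistant% × (1 − wt_clone_fraction)

  (one decimal, round half up), and firefly/renilla reporter normalization
  with the induction range max(mean)/min(mean) over non-reference
  conditions.
* **Fixtures** (`fixtures`): deterministic mock entry/destination vectors,
  standard parts and genomes with planted targets, so every stage is
  testable offline.
* **Workflows** (`workflow`, `config`): YAML/dict-driven multi-step builds
  over a flat JSON part registry, with a traceable build report, plus
  YAML-overridable enzyme/fusion-site configuration.

## Worked example

```python
import gbcrispr as gb

config = gb.default_config()
fx = gb.FixtureConfig(seed=1)
parts = gb.standard_parts(fx, config)
alpha1 = gb.make_vector("alpha", fx, config, position=1)

duplex = gb.domesticate_target("GATCATCATCATCATCATCA", "D", config)
print(duplex.fwd_oligo)   # ATTGGATCATCATCATCATCATCA
print(duplex.rev_oligo)   # AAACTGATGATGATGATGATGATC

tu = gb.assemble_grna_cassette(
    parts["polIII_promoter"], duplex, parts["scaffold_D"], alpha1, config)
print(tu.klass, len(tu.molecule))          # alpha 2906
print(gb.corrected_mutation_rate(17, 0.29))  # 12.1
```

The two oligos are the only target-specific inputs of a whole guide-RNA
cassette: the 20-mer flanked by the fusion sites of the D-element syntax
(`ATTG…`/`AAAC…`). The assembled 2906-bp plasmid is the complete
PolIII-driven guide cassette hosted in the α1 destination, ready for a
binary (braid) reaction. The last line applies the wild-type-clone
correction to a PCR/RE assay measuring 17% digestion-resistant amplicons
of which 29% sequenced as wild type: corrected editing rate 12.1%.

The `examples/` directory holds one short script per capability
(target scanning, cassette design, polycistronic multiplexing, clone
validation, reporter normalization, declarative workflows); each builds its
own inputs and prints what it computes.

## Acceptance script

`scripts/acceptance.py` re-runs the package's assay arithmetic from scratch
on the published PCR/RE inputs (after exercising the full multiplex build
once as a self-check) and writes the corrected mutation rates as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
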