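"""Clone and edit validation: predicted restriction bands for screening
assembled plasmids, a PCR/RE loss-of-site assay design, and the corrected
mutation-rate arithmetic applied to published-style assay numbers."""

import random

import gbcrispr as gb
from gbcrispr.fixtures import scrub

config = gb.default_config()

# --- band prediction for a plasmid screen ------------------------------
rng = random.Random(7)
seq = scrub("".join(rng.choice("ACGT") for _ in range(8075)), ("GGATCC",))
seq = seq[:100] + "GGATCC" + seq[106:1501] + "GGATCC" + seq[1507:]
plasmid = gb.DNAMolecule("level2_clone", seq, gb.CIRCULAR)
pattern = gb.predict_bands(plasmid, "BamHI")
print(f"{plasmid.id} ({len(plasmid)} bp) BamHI bands: {pattern.bands}")
# a correct clone shows exactly these two bands on the gel

# --- PCR/RE redetection assay ------------------------------------------
proto = "G" + "A" * 13 + "ACTAGT"  # SpeI recognition straddles the cut
flank = scrub("".join(rng.choice("ACGT") for _ in range(280)), ("ACTAGT", proto))
amplicon = gb.DNAMolecule("amp", flank + proto + "TGG" + flank, gb.LINEAR)
target = gb.TargetSpec("XT2-like", proto, "TGG", "+", len(flank))
assay = gb.design_redetection_assay(target, amplicon, ["SpeI", "EcoRI", "BamHI"])
print(
    f"diagnostic enzyme: {assay.enzyme}; wild-type bands {assay.wt_bands}, "
    f"mutant signature {assay.mutant_bands}"
)
print(f"excluded: {assay.excluded}")

# --- corrected mutation rate -------------------------------------------
# raw RE-resistant fractions overestimate editing: some resistant clones
# sequence as wild type, so the raw rate is scaled by (1 - wt fraction)
for name, raw, wt in (("XT1", 17.0, 0.29), ("XT2", 14.5, 0.32)):
    rate = gb.corrected_mutation_rate(raw, wt)
    print(f"{name}: raw {raw}% resistant, {wt:.0%} wild-type clones "
          f"-> corrected mutation rate {rate}%")
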