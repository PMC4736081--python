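"""Second-dimension multiplexing: five guides against seven genes on one
T-DNA. Two polycistronic tRNA-gRNA units (2 and 3 slots) are built from
level -1 tRNA-scaffold plasmids and combined in a binary reaction into a
single omega-hosted level-2 construct."""

import gbcrispr as gb

config = gb.default_config()
demo = gb.multiplex_demo(seed=1, config=config)

print(f"mock genome: {len(demo['genome'])} bp, 7 gene regions")
genes_per_guide = {}
for row in demo["truth"]:
    genes_per_guide.setdefault(row["protospacer"], []).append(row["gene_id"])
for proto, genes in genes_per_guide.items():
    print(f"  guide {proto} -> {', '.join(genes)}")

for key in ("poly_xt", "poly_fuct", "level2"):
    rec = demo[key]
    trnas = rec.insert.count(config.trna_seq)
    print(
        f"{rec.part_id}: {rec.klass}-hosted, {len(rec.molecule)} bp, "
        f"{trnas} tRNA-gRNA slot(s)"
    )

level2 = demo["level2"]
n_genes = len({r["gene_id"] for r in demo["truth"]})
print(
    f"-> one binary plasmid carries all "
    f"{level2.insert.count(config.trna_seq)} guides targeting {n_genes} genes"
)
# validation digest a screener would run on miniprep DNA:
for enzyme in ("EcoRI", "BamHI"):
    pattern = gb.predict_bands(level2.molecule, enzyme)
    bands = pattern.bands if not pattern.uncut else "uncut"
    print(f"expected {enzyme} bands: {bands}")
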