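"""File I/O: FASTA/GenBank molecules (via Biopython), oligo order sheets,
truth tables and reporter CSV tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .errors import GBError
from .molecules import CIRCULAR, LINEAR, DNAMolecule


def molecule_to_record(mol: DNAMolecule) -> SeqRecord:
    rec = SeqRecord(Seq(mol.sequence), id=mol.id, name=mol.id[:16], description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if mol.is_circular else "linear"
    for label, start, end, strand in mol.annotations:
        loc = FeatureLocation(start, min(end, len(mol.sequence)),
                              strand=1 if strand == "+" else -1)
        rec.features.append(
            SeqFeature(loc, type="misc_feature", qualifiers={"label": [label]})
        )
    return rec


def record_to_molecule(rec: SeqRecord, topology: str | None = None) -> DNAMolecule:
    topo = topology or rec.annotations.get("topology", LINEAR)
    topo = CIRCULAR if topo == "circular" else LINEAR
    annotations = []
    for feat in rec.features:
        label = feat.qualifiers.get("label", [feat.type])[0]
        strand = "-" if feat.location.strand == -1 else "+"
        annotations.append(
            (label, int(feat.location.start), int(feat.location.end), strand)
        )
    return DNAMolecule(rec.id, str(rec.seq), topo, annotations)


def read_molecules(path, fmt: str | None = None, circular: bool = False):
    """Read FASTA or GenBank into molecules. FASTA defaults to linear;
    pass ``circular=True`` to override. GenBank topology comes from the
    LOCUS line."""
    path = Path(path)
    if fmt is None:
        fmt = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".genbank") else "fasta"
    mols = []
    for rec in SeqIO.parse(str(path), fmt):
        override = CIRCULAR if (fmt == "fasta" and circular) else None
        mols.append(record_to_molecule(rec, topology=override))
    if not mols:
        raise GBError(f"no sequences in {path}")
    return mols


def write_molecules(mols, path, fmt: str | None = None):
    path = Path(path)
    if fmt is None:
        fmt = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".genbank") else "fasta"
    records = [molecule_to_record(m) for m in mols]
    SeqIO.write(records, str(path), fmt)


# The reaction conditions recommended in the source protocol; the primary
# text recommends 1 uM oligo concentration while the detailed protocol uses
# 0.1 uM — both are recorded here verbatim rather than silently reconciled.
PROTOCOL_NOTE = (
    "anneal oligos 30 min at room temperature in water; "
    "recommended oligo concentration 1 uM (results) / 0.1 uM (methods)"
)


def write_order_sheet(duplexes: dict, path):
    """TSV oligo order sheet: name, sequence 5'->3' (fwd/rev per target)."""
    rows = []
    for name, duplex in duplexes.items():
        rows.append({"name": f"{name}_F", "sequence_5to3": duplex.fwd_oligo})
        rows.append({"name": f"{name}_R", "sequence_5to3": duplex.rev_oligo})
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# {PROTOCOL_NOTE}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_truth_table(rows, path):
    df = pd.DataFrame(rows)
    if "diagnostic" in df.columns:
        df["diagnostic"] = df["diagnostic"].map(lambda d: ",".join(d))
    df.to_csv(path, sep="\t", index=False)


def read_reporter_csv(path) -> pd.DataFrame:
    """Reporter data CSV with columns condition, replicate, fluc, rluc."""
    df = pd.read_csv(path)
    missing = {"condition", "fluc", "rluc"} - set(df.columns)
    if missing:
        raise GBError(f"reporter CSV missing columns: {sorted(missing)}")
    return df
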