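"""Declarative build workflows and the flat part registry.

A workflow is a list of steps (domesticate / cassette / polycistron /
binary / bands) over a registry of parts and destination vectors; running
it yields the construct set plus a machine-readable build report whose
entries list, for every construct, the inputs it came from and the
validation digests to expect — enough to re-derive any construct from its
listed inputs (full genealogy/traceability).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .assay import predict_bands
from .config import ToolConfig, default_config
from .design import (
    PolycistronDesign,
    assemble_grna_cassette,
    build_polycistron,
    domesticate_target,
)
from .errors import GBError, WorkflowError
from .fixtures import FixtureConfig, make_vector, minus1_part, standard_parts
from .grammar import GBPartRecord, VectorSpec, binary_assemble
from .io import write_molecules
from .molecules import DNAMolecule

_VALIDATION_PANEL = ("EcoRI", "BamHI", "HindIII")


@dataclass
class PartRegistry:
    """Flat part registry: part_id -> record; JSON on disk, not a service."""

    parts: dict = field(default_factory=dict)
    vectors: dict = field(default_factory=dict)

    def add(self, record: GBPartRecord):
        self.parts[record.part_id] = record

    def add_vector(self, vec: VectorSpec):
        self.vectors[vec.vector_id] = vec

    def part(self, part_id: str) -> GBPartRecord:
        try:
            return self.parts[part_id]
        except KeyError:
            raise WorkflowError(f"unknown part id {part_id!r}") from None

    def vector(self, vector_id: str) -> VectorSpec:
        try:
            return self.vectors[vector_id]
        except KeyError:
            raise WorkflowError(f"unknown vector id {vector_id!r}") from None

    def to_json(self, path):
        payload = {
            pid: {
                "name": r.name,
                "level": r.level,
                "syntax": list(r.syntax),
                "backbone": r.backbone_id,
                "sequence": r.molecule.sequence if r.molecule else "",
                "topology": r.molecule.topology if r.molecule else "circular",
            }
            for pid, r in self.parts.items()
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path):
        payload = json.loads(Path(path).read_text())
        reg = cls()
        for pid, meta in payload.items():
            reg.add(
                GBPartRecord(
                    part_id=pid,
                    name=meta["name"],
                    level=meta["level"],
                    syntax=meta.get("syntax", []),
                    backbone_id=meta.get("backbone", ""),
                    molecule=DNAMolecule(pid, meta["sequence"], meta["topology"])
                    if meta.get("sequence")
                    else None,
                )
            )
        return reg


def fixture_registry(seed: int = 1, config: ToolConfig | None = None) -> PartRegistry:
    """Registry pre-populated with the fixture part kit and destination
    vectors alpha1/alpha2/omega1/omega2 (plus an entry vector)."""
    config = config or default_config()
    cfg = FixtureConfig(seed=seed)
    reg = PartRegistry()
    for record in standard_parts(cfg, config).values():
        reg.add(record)
    reg.add_vector(make_vector("entry", cfg, config, vector_id="pUPD"))
    for klass in ("alpha", "omega"):
        for pos in (1, 2):
            reg.add_vector(
                make_vector(klass, cfg, config, position=pos,
                            vector_id=f"{klass}{pos}")
            )
    return reg


def _construct_report(record: GBPartRecord, inputs: list[str], config) -> dict:
    digests = {}
    for name in _VALIDATION_PANEL:
        pattern = predict_bands(record.molecule, config.enzyme(name))
        digests[name] = pattern.bands if not pattern.uncut else "uncut"
    release = "BsmBI" if record.klass == "alpha" else "BsaI"
    digests[release] = predict_bands(record.molecule, config.enzyme(release)).bands
    return {
        "part_id": record.part_id,
        "level": record.level,
        "klass": record.klass,
        "length_bp": len(record.molecule),
        "inputs": inputs,
        "syntax": list(record.syntax),
        "validation_digests": digests,
    }


def run_workflow(
    spec,
    registry: PartRegistry | None = None,
    config: ToolConfig | None = None,
    out_dir=None,
    seed: int = 1,
):
    """Execute a workflow spec (dict, or path to a YAML file).

    Returns ``(constructs, report)`` where ``constructs`` maps step ids to
    part records and ``report`` is the JSON-serializable build report.
    Unknown ids, malformed steps or assembly failures raise
    :class:`WorkflowError` carrying the failing step id.
    """
    if not isinstance(spec, dict):
        with open(spec) as fh:
            spec = yaml.safe_load(fh) or {}
    if not isinstance(spec.get("steps", []), list):
        raise WorkflowError("workflow spec: 'steps' must be a list")
    config = config or default_config()
    registry = registry or fixture_registry(seed=seed, config=config)

    constructs: dict[str, GBPartRecord] = {}
    duplexes = {}
    report = {"steps": [], "constructs": {}, "binary_steps": 0}

    def resolve_part(pid):
        if pid in constructs:
            return constructs[pid]
        return registry.part(pid)

    for i, step in enumerate(spec.get("steps", [])):
        op = step.get("op")
        sid = step.get("id", f"step{i}")
        try:
            if op == "domesticate":
                duplex = domesticate_target(
                    step["protospacer"], step.get("mode", "D"), config,
                    policy_5G=step.get("policy_5G"),
                )
                duplexes[sid] = duplex
                report["steps"].append(
                    {"id": sid, "op": op,
                     "fusion_sites": [duplex.left_fusion, duplex.right_fusion],
                     "oligos": [duplex.fwd_oligo, duplex.rev_oligo]}
                )
            elif op == "cassette":
                if step["target"] not in duplexes:
                    raise WorkflowError(f"unknown target id {step['target']!r}")
                record = assemble_grna_cassette(
                    resolve_part(step["promoter"]),
                    duplexes[step["target"]],
                    resolve_part(step["scaffold"]),
                    registry.vector(step["destination"]),
                    config,
                    part_id=sid,
                )
                constructs[sid] = record
                inputs = [step["promoter"], step["target"], step["scaffold"],
                          step["destination"]]
                report["steps"].append({"id": sid, "op": op, "inputs": inputs})
                report["constructs"][sid] = _construct_report(record, inputs, config)
            elif op == "polycistron":
                protos = step["targets"]
                n = len(protos)
                slot_parts = [
                    minus1_part(k, n, FixtureConfig(seed=seed), config)
                    for k in range(1, n + 1)
                ]
                record = build_polycistron(
                    PolycistronDesign(
                        ordered_targets=protos,
                        position_parts=slot_parts,
                        promoter_part=resolve_part(
                            step.get("promoter", "GB_U3p")
                        ),
                    ),
                    registry.vector(step["destination"]),
                    config,
                    part_id=sid,
                )
                constructs[sid] = record
                inputs = list(protos) + [step["destination"]]
                report["steps"].append({"id": sid, "op": op, "inputs": inputs})
                report["constructs"][sid] = _construct_report(record, inputs, config)
            elif op == "binary":
                record = binary_assemble(
                    resolve_part(step["a"]),
                    resolve_part(step["b"]),
                    registry.vector(step["destination"]),
                    config,
                    part_id=sid,
                )
                constructs[sid] = record
                inputs = [step["a"], step["b"], step["destination"]]
                report["binary_steps"] += 1
                report["steps"].append({"id": sid, "op": op, "inputs": inputs})
                report["constructs"][sid] = _construct_report(record, inputs, config)
            elif op == "bands":
                record = resolve_part(step["construct"])
                pattern = predict_bands(
                    record.molecule, config.enzyme(step["enzyme"])
                )
                report["steps"].append(
                    {"id": sid, "op": op, "enzyme": step["enzyme"],
                     "bands": pattern.bands, "uncut": pattern.uncut}
                )
            else:
                raise WorkflowError(f"step {sid}: unknown op {op!r}")
        except KeyError as exc:
            raise WorkflowError(f"step {sid} ({op}): missing field {exc}") from exc
        except WorkflowError:
            raise
        except GBError as exc:
            raise WorkflowError(f"step {sid} ({op}): {exc}") from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sid, record in constructs.items():
            write_molecules([record.molecule], out / f"{sid}.gb")
        (out / "report.json").write_text(json.dumps(report, indent=1))
    return constructs, report
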