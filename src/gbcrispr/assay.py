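"""Clone validation and assay arithmetic.

Three desk-side computations accompany the cloning simulator:

* restriction-digest band prediction for verifying assembled plasmids on a
  gel (circular, k sites -> k bands summing to the plasmid length);
* design of the PCR/RE loss-of-site mutation assay: pick a panel enzyme
  whose only site in the amplicon overlaps the Cas9 cut, so editing shows
  up as a digestion-resistant full-length band;
* the corrected mutation rate: the raw RE-resistant amplicon fraction
  over-counts editing because some resistant clones turn out wild type on
  sequencing, so the raw rate is scaled by (1 - wild-type clone fraction);
* firefly/renilla reporter normalization: per-condition mean Fluc/Rluc
  ratios scaled so the reference condition is exactly 1, plus the induction
  range between the strongest activation and the strongest repression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .config import STANDARD_ENZYMES
from .design import TargetSpec
from .digestion import find_sites
from .errors import DesignError, GBError, SequenceError
from .molecules import DNAMolecule, EnzymeSpec, revcomp


@dataclass
class DigestPattern:
    """Predicted gel bands for one enzyme, largest first."""

    enzyme: str
    bands: list[int]
    uncut: bool = False


@dataclass
class MutationAssay:
    """PCR/RE assay numbers with the wild-type-clone correction applied."""

    raw_resistant_frac: float  # RE-resistant amplicon fraction, 0..1
    wt_clone_frac: float  # wild-type fraction among sequenced resistant clones

    def __post_init__(self):
        if not (0 <= self.raw_resistant_frac <= 1):
            raise DesignError("raw_resistant_frac must be in [0, 1]")
        if not (0 <= self.wt_clone_frac <= 1):
            raise DesignError("wt_clone_frac must be in [0, 1]")

    @property
    def corrected_rate_pct(self) -> float:
        return corrected_mutation_rate(
            100.0 * self.raw_resistant_frac, self.wt_clone_frac
        )


@dataclass
class ReporterSample:
    """One firefly/renilla co-transfection readout."""

    condition: str
    fluc: float
    rluc: float

    def __post_init__(self):
        if self.rluc <= 0:
            raise DesignError(f"{self.condition}: rluc must be > 0")

    @property
    def ratio(self) -> float:
        return self.fluc / self.rluc


@dataclass
class ReporterSummary:
    """Per-condition normalized means and the overall induction range."""

    per_condition: dict  # condition -> (mean, sd, n)
    reference: str
    induction_range: float


@dataclass
class RedetectionAssay:
    """Chosen diagnostic enzyme with wild-type and mutant band signatures."""

    enzyme: str | None
    wt_bands: list[int] = field(default_factory=list)
    mutant_bands: list[int] = field(default_factory=list)
    excluded: list = field(default_factory=list)  # (enzyme, reason)
    advisory: str | None = None


def _resolve_enzyme(enzyme) -> EnzymeSpec:
    if isinstance(enzyme, EnzymeSpec):
        return enzyme
    try:
        return STANDARD_ENZYMES[enzyme]
    except KeyError:
        raise SequenceError(f"unknown enzyme {enzyme!r}") from None


def predict_bands(mol: DNAMolecule, enzyme) -> DigestPattern:
    """Expected restriction-band lengths for ``mol`` cut by ``enzyme``
    (an :class:`EnzymeSpec` or the name of a panel standard enzyme)."""
    ez = _resolve_enzyme(enzyme)
    sites = find_sites(mol, ez)
    cuts = sorted({s.cut_top % len(mol) if mol.is_circular else s.cut_top
                   for s in sites})
    n = len(mol)
    if not cuts:
        if mol.is_circular:
            return DigestPattern(ez.name, [], uncut=True)
        return DigestPattern(ez.name, [n])
    if mol.is_circular:
        bands = [
            (b - a) % n or n
            for a, b in zip(cuts, cuts[1:] + [cuts[0]])
        ]
    else:
        edges = [0] + cuts + [n]
        bands = [b - a for a, b in zip(edges, edges[1:]) if b > a]
    return DigestPattern(ez.name, sorted(bands, reverse=True))


def design_redetection_assay(
    target: TargetSpec, amplicon: DNAMolecule, panel
) -> RedetectionAssay:
    """Select a loss-of-site diagnostic enzyme for re-detecting mutations.

    The amplicon must contain the protospacer exactly once. A qualifying
    enzyme has exactly one site in the amplicon, and that site's
    recognition span strictly contains the Cas9 cut. The wild-type
    signature is the two-band digest; mutants resist digestion and run as
    one full-length band.
    """
    seq = amplicon.sequence
    occurrences = []
    for strand, pattern in (("+", target.protospacer),
                            ("-", revcomp(target.protospacer))):
        i = seq.find(pattern)
        while i != -1:
            occurrences.append((strand, i))
            i = seq.find(pattern, i + 1)
    if len(occurrences) != 1:
        raise DesignError(
            f"amplicon contains the protospacer {len(occurrences)} times; need 1"
        )
    strand, start = occurrences[0]
    cut = start + target.cut_offset if strand == "+" else start + 20 - target.cut_offset

    excluded, qualifying = [], []
    for enzyme in panel:
        ez = _resolve_enzyme(enzyme)
        k = ez.site_len
        spans = set()
        for pat in {ez.recognition, revcomp(ez.recognition)}:
            j = seq.find(pat)
            while j != -1:
                spans.add(j)
                j = seq.find(pat, j + 1)
        if len(spans) == 0:
            excluded.append((ez.name, "no site in amplicon"))
        elif len(spans) > 1:
            excluded.append((ez.name, f"{len(spans)} sites in amplicon"))
        elif not (min(spans) < cut < min(spans) + k):
            excluded.append((ez.name, "site does not overlap the cut"))
        else:
            qualifying.append(ez)
    if qualifying:
        chosen = qualifying[0]
        wt = predict_bands(amplicon, chosen)
        return RedetectionAssay(
            enzyme=chosen.name,
            wt_bands=wt.bands,
            mutant_bands=[len(amplicon)],
            excluded=excluded,
        )
    return RedetectionAssay(
        enzyme=None,
        excluded=excluded,
        advisory="no diagnostic assay: no panel enzyme has a unique site "
        "overlapping the cut",
    )


def corrected_mutation_rate(raw_pct: float, wt_clone_frac: float) -> float:
    """Mutation rate corrected for wild-type clones among resistant reads.

    ``raw_pct`` is the RE-resistant amplicon percentage; the corrected
    rate is ``raw_pct * (1 - wt_clone_frac)``, reported in percent rounded
    to one decimal (half up). Monotone decreasing in ``wt_clone_frac`` and
    never exceeds the raw rate.
    """
    if not (0 <= raw_pct <= 100):
        raise DesignError("raw_pct must be in [0, 100]")
    if not (0 <= wt_clone_frac <= 1):
        raise DesignError("wt_clone_frac must be in [0, 1]")
    value = Decimal(str(raw_pct)) * (1 - Decimal(str(wt_clone_frac)))
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def normalize_reporter(samples, reference: str) -> ReporterSummary:
    """Normalize Fluc/Rluc ratios to a reference condition set to 1.

    ``samples`` is a list of :class:`ReporterSample` or a DataFrame with
    columns condition/fluc/rluc. Per-condition means use the sample SD
    (n-1). The induction range is max(mean)/min(mean) over non-reference
    conditions — the fold span between strongest activation and strongest
    repression.
    """
    if isinstance(samples, pd.DataFrame):
        df = samples.copy()
        required = {"condition", "fluc", "rluc"}
        if not required <= set(df.columns):
            raise GBError(f"reporter table needs columns {sorted(required)}")
    else:
        df = pd.DataFrame(
            [{"condition": s.condition, "fluc": s.fluc, "rluc": s.rluc}
             for s in samples]
        )
    if df.empty:
        raise GBError("no reporter samples")
    if (df["rluc"] <= 0).any():
        raise GBError("rluc must be > 0 in all samples")
    if reference not in set(df["condition"]):
        raise GBError(f"reference condition {reference!r} missing")

    df["ratio"] = df["fluc"] / df["rluc"]
    ref_mean = df.loc[df["condition"] == reference, "ratio"].mean()
    df["norm"] = df["ratio"] / ref_mean

    per_condition = {}
    for cond, grp in df.groupby("condition", sort=False):
        vals = grp["norm"].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        per_condition[cond] = (float(np.mean(vals)), sd, len(vals))

    others = [m for c, (m, _, _) in per_condition.items() if c != reference]
    induction = max(others) / min(others) if others else 1.0
    return ReporterSummary(
        per_condition=per_condition, reference=reference,
        induction_range=float(induction),
    )
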