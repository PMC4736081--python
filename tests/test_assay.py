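import random

import numpy as np
import pandas as pd
import pytest

import gbcrispr as gb
from gbcrispr.fixtures import scrub

CFG = gb.default_config()


# ------------------------------------------------------------ bands


def _circular_with(sites, length, enzyme_rec, seed=0):
    rng = random.Random(seed)
    seq = list(scrub("".join(rng.choice("ACGT") for _ in range(length)),
                     (enzyme_rec,)))
    for pos in sites:
        seq[pos : pos + len(enzyme_rec)] = list(enzyme_rec)
    return gb.DNAMolecule("m", "".join(seq), gb.CIRCULAR)


def test_two_site_circular_band_pattern():
    """Two BamHI cuts 1401 bp apart on an 8075-bp plasmid: bands 6674+1401,
    mirroring a level-2 construct validation digest."""
    m = _circular_with([100, 1501], 8075, "GGATCC")
    pattern = gb.predict_bands(m, "BamHI")
    assert pattern.bands == [6674, 1401]
    assert sum(pattern.bands) == len(m)


def test_uncut_circular_reported():
    m = _circular_with([], 3000, "GAATTC")
    pattern = gb.predict_bands(m, "EcoRI")
    assert pattern.uncut and pattern.bands == []


def test_linear_single_cut():
    seq = scrub("".join(random.Random(1).choice("ACGT") for _ in range(100)),
                ("ACTAGT",))
    seq = seq[:39] + "ACTAGT" + seq[45:]  # SpeI A^CTAGT -> cut at 40
    m = gb.DNAMolecule("m", seq, gb.LINEAR)
    assert gb.predict_bands(m, "SpeI").bands == [60, 40]


@pytest.mark.parametrize("seed", range(10))
def test_band_conservation_random(seed):
    rng = random.Random(seed)
    name = rng.choice(["EcoRI", "BamHI", "HindIII", "SpeI"])
    rec = CFG.enzyme(name).recognition
    n = rng.randrange(500, 4000)
    positions = sorted(rng.sample(range(0, n - 10, 10), rng.randrange(0, 5)))
    positions = [p for i, p in enumerate(positions)
                 if i == 0 or p - positions[i - 1] > 12]
    m = _circular_with(positions, n, rec, seed=seed)
    pattern = gb.predict_bands(m, name)
    if pattern.uncut:
        assert positions == []
    else:
        assert sum(pattern.bands) == len(m)
        assert pattern.bands == sorted(pattern.bands, reverse=True)


# ------------------------------------------------- redetection assay


def _amplicon_with_target(proto, flank_left=300, flank_right=280, seed=3):
    rng = random.Random(seed)
    left = scrub("".join(rng.choice("ACGT") for _ in range(flank_left)),
                 ("ACTAGT", proto))
    right = scrub("".join(rng.choice("ACGT") for _ in range(flank_right)),
                  ("ACTAGT", proto))
    return gb.DNAMolecule("amp", left + proto + "TGG" + right, gb.LINEAR)


def test_redetection_picks_overlapping_enzyme():
    proto = "G" + "A" * 13 + "ACTAGT"  # SpeI straddles the cut at offset 17
    amp = _amplicon_with_target(proto)
    target = gb.TargetSpec("g", proto, "TGG", "+", 300)
    assay = gb.design_redetection_assay(target, amp, ["SpeI", "EcoRI"])
    assert assay.enzyme == "SpeI"
    assert len(assay.wt_bands) == 2 and sum(assay.wt_bands) == len(amp)
    assert assay.mutant_bands == [len(amp)]
    assert ("EcoRI", "no site in amplicon") in assay.excluded


def test_redetection_excludes_multi_site_enzyme():
    proto = "G" + "A" * 13 + "ACTAGT"
    amp = _amplicon_with_target(proto)
    seq = amp.sequence[:50] + "ACTAGT" + amp.sequence[56:]  # second SpeI site
    amp2 = gb.DNAMolecule("amp2", seq, gb.LINEAR)
    target = gb.TargetSpec("g", proto, "TGG", "+", 300)
    assay = gb.design_redetection_assay(target, amp2, ["SpeI"])
    assert assay.enzyme is None
    assert ("SpeI", "2 sites in amplicon") in assay.excluded


def test_redetection_empty_panel_advisory():
    proto = "G" + "A" * 13 + "ACTAGT"
    amp = _amplicon_with_target(proto)
    target = gb.TargetSpec("g", proto, "TGG", "+", 300)
    assay = gb.design_redetection_assay(target, amp, [])
    assert assay.enzyme is None and "no diagnostic assay" in assay.advisory


# -------------------------------------------------- mutation rate


def test_corrected_mutation_rate_published_values():
    assert gb.corrected_mutation_rate(17, 0.29) == 12.1
    assert gb.corrected_mutation_rate(14.5, 0.32) == 9.9


@pytest.mark.parametrize("raw", [0.0, 7.3, 50.0, 100.0])
def test_corrected_rate_boundary_identities(raw):
    assert gb.corrected_mutation_rate(raw, 0.0) == round(raw, 1)
    assert gb.corrected_mutation_rate(raw, 1.0) == 0.0


def test_corrected_rate_monotone_and_bounded():
    rates = [gb.corrected_mutation_rate(40, w / 10) for w in range(11)]
    assert rates == sorted(rates, reverse=True)
    assert all(r <= 40 for r in rates)
    with pytest.raises(gb.DesignError):
        gb.corrected_mutation_rate(101, 0.1)
    with pytest.raises(gb.DesignError):
        gb.corrected_mutation_rate(10, 1.5)


def test_corrected_rate_rounds_half_up():
    assert gb.corrected_mutation_rate(25.0, 0.5) == 12.5
    assert gb.corrected_mutation_rate(24.9, 0.5) == 12.5  # 12.45 -> 12.5


# ---------------------------------------------------- reporter ratios


def _triplicates(cond, ratio, rluc=1000.0):
    return [gb.ReporterSample(cond, ratio * rluc, rluc) for _ in range(3)]


def test_reference_normalizes_to_exactly_one():
    samples = _triplicates("REF", 2.0) + _triplicates("A", 2.0) + _triplicates("B", 2.0)
    s = gb.normalize_reporter(samples, "REF")
    assert s.per_condition["REF"][0] == 1.0
    assert s.per_condition["A"][0] == 1.0
    assert s.induction_range == 1.0


def test_induction_range_covers_repression_and_activation():
    samples = (
        _triplicates("REF", 1.0) + _triplicates("repressed", 0.5)
        + _triplicates("activated", 3.25)
    )
    s = gb.normalize_reporter(samples, "REF")
    assert s.per_condition["repressed"][0] == pytest.approx(0.5)
    assert s.per_condition["activated"][0] == pytest.approx(3.25)
    assert s.induction_range == pytest.approx(6.5)


def test_scale_invariance():
    samples = _triplicates("REF", 1.0) + _triplicates("A", 0.3)
    base = gb.normalize_reporter(samples, "REF")
    scaled = [gb.ReporterSample(x.condition, x.fluc * 37.0, x.rluc) for x in samples]
    s2 = gb.normalize_reporter(scaled, "REF")
    for cond in base.per_condition:
        assert s2.per_condition[cond][0] == pytest.approx(base.per_condition[cond][0])
    assert s2.induction_range == pytest.approx(base.induction_range)


def test_noisy_triplicates_recover_truth_within_3sd():
    rng = np.random.default_rng(42)
    truth = {"REF": 1.0, "low": 0.4, "high": 2.5}
    samples = []
    for cond, ratio in truth.items():
        for _ in range(3):
            noise = float(np.exp(rng.normal(0, 0.05)))
            samples.append(gb.ReporterSample(cond, 1000 * ratio * noise, 1000))
    s = gb.normalize_reporter(samples, "REF")
    for cond in ("low", "high"):
        mean, sd, n = s.per_condition[cond]
        assert n == 3
        assert abs(mean - truth[cond]) < max(3 * sd, 0.05)


def test_missing_reference_and_bad_rluc():
    with pytest.raises(gb.GBError, match="missing"):
        gb.normalize_reporter(_triplicates("A", 1.0), "REF")
    with pytest.raises(gb.DesignError):
        gb.ReporterSample("A", 10.0, 0.0)


def test_dataframe_input_round_trip(tmp_path):
    df = pd.DataFrame(
        {
            "condition": ["REF"] * 3 + ["A"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
            "fluc": [100, 110, 90, 260, 240, 250],
            "rluc": [100, 100, 100, 100, 100, 100],
        }
    )
    path = tmp_path / "reporter.csv"
    df.to_csv(path, index=False)
    from gbcrispr.io import read_reporter_csv

    s = gb.normalize_reporter(read_reporter_csv(path), "REF")
    assert s.per_condition["A"][0] == pytest.approx(2.5)
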