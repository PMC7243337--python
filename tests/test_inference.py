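"""146-bp classifier, feature association, ratios, reconstruction, fold-back."""

import numpy as np
import pytest

from telochec import inference
from telochec.caller import BandCall, PreferentialSite
from telochec.chec_sim import DigestionParams, LaneId
from telochec.inference import (accessibility_ratio, classify_intervals,
                                foldback_test, pattern_divergence,
                                reconstruct_model)
from telochec.templates import build_template


def _sites(offsets, sds=None, labels=None):
    sds = sds or [0.0] * len(offsets)
    labels = labels or [chr(ord("A") + i) for i in range(len(offsets))]
    return [
        PreferentialSite(lab, off, sd, 4, ("GBD-MN",))
        for lab, off, sd in zip(labels, offsets, sds)
    ]


@pytest.mark.parametrize(
    "spacing,klass",
    [(106.0, "sub_nucleosomal"), (152.0, "nucleosome_compatible"),
     (146.0, "nucleosome_compatible"), (145.9, "sub_nucleosomal")],
)
def test_146_bp_threshold_rule(spacing, klass):
    (iv,) = classify_intervals(_sites([100.0, 100.0 + spacing]))
    assert iv.klass == klass


def test_spacing_sd_propagates_in_quadrature():
    (iv,) = classify_intervals(_sites([100.0, 260.0], sds=[3.0, 4.0]))
    assert iv.spacing_sd == pytest.approx(5.0)


def test_classifier_is_permutation_invariant():
    offs = [900.0, 100.0, 500.0, 300.0]
    a = classify_intervals(_sites(offs))
    b = classify_intervals(_sites(sorted(offs)))
    assert [(iv.spacing_mean, iv.klass) for iv in a] == [
        (iv.spacing_mean, iv.klass) for iv in b
    ]


def test_fewer_than_two_sites_yields_no_intervals():
    assert classify_intervals(_sites([100.0])) == []


def test_acs_association_on_control_locus():
    t = build_template("TRP1ARS1")
    sites = _sites([s.offset for s in t.ground_truth_sites],
                   labels=[s.label for s in t.ground_truth_sites])
    intervals = classify_intervals(sites, t)
    by_pair = {(iv.left_label, iv.right_label): iv for iv in intervals}
    acs_iv = by_pair[("II", "III")]
    assert acs_iv.klass == "sub_nucleosomal"
    assert acs_iv.association == "ORC_ACS"
    assert by_pair[("I", "II")].klass == "nucleosome_compatible"
    assert by_pair[("III", "IV")].klass == "nucleosome_compatible"


def test_grf_array_association_at_yptrf_junction():
    t = build_template("YpTRF")
    gt = sorted(t.ground_truth_sites, key=lambda s: s.offset)
    sites = _sites([s.offset for s in gt], labels=[s.label for s in gt])
    intervals = classify_intervals(sites, t)
    junction_iv = intervals[-1]  # interval abutting the TG repeats (I-II)
    assert junction_iv.association == "Tbf1_Reb1_array"


def _ratio_inputs(percents):
    """One synthetic MN lane with bands matched to sites I, II, III."""
    t = build_template("YpTRF")
    offsets = {"I": 890.0, "II": 690.0, "III": 584.0}
    sites = [PreferentialSite(lab, off, 2.0, 4, ("MN-Rap1",))
             for lab, off in offsets.items()]
    lane = LaneId("YpTRF", "WT", "MN-Rap1", 2.0, "30C")
    bands = [BandCall(lane, 0.0, offsets[lab], pct, 0.5)
             for lab, pct in percents.items()]
    return {lane: bands}, sites, t


def test_ratio_arithmetic():
    lane_bands, sites, t = _ratio_inputs({"I": 17.4, "II": 12.0, "III": 8.0})
    r = accessibility_ratio(lane_bands, sites, t, "MN-Rap1")
    assert r.value == pytest.approx(17.4 / 20.0)
    assert not r.below_detection


def test_ratio_zero_when_numerator_absent():
    lane_bands, sites, t = _ratio_inputs({"II": 12.0, "III": 8.0})
    r = accessibility_ratio(lane_bands, sites, t, "MN-Rap1")
    assert r.value == pytest.approx(0.0)


def test_ratio_flagged_below_detection_limit():
    lane_bands, sites, t = _ratio_inputs({"I": 17.4})
    r = accessibility_ratio(lane_bands, sites, t, "MN-Rap1")
    assert r.below_detection and r.value is None


def test_uniform_array_reconstructs_all_nucleosomes():
    t = build_template("TRP1ARS1")
    sites = _sites([100.0, 265.0, 430.0, 595.0])
    # strip features so no association can fire
    from dataclasses import replace

    bare = replace(t, features=tuple(f for f in t.features
                                     if f.kind in ("restriction_site", "probe")))
    model = reconstruct_model(classify_intervals(sites, bare), bare)
    assert all(kind == "nucleosome" for *_, kind in model.occupants)
    assert not model.terminal_nfr


def test_control_locus_orc_flanked_by_nucleosomes():
    t = build_template("TRP1ARS1")
    gt = t.ground_truth_sites
    sites = _sites([s.offset for s in gt], labels=[s.label for s in gt])
    model = reconstruct_model(classify_intervals(sites, t), t)
    kinds = [k for *_, k in model.occupants]
    i = kinds.index("ORC")
    assert kinds[i - 1] == "nucleosome" and kinds[i + 1] == "nucleosome"
    assert model.orc_site and not model.terminal_nfr


def test_divergence_of_identical_patterns_is_zero():
    sites = _sites([100.0, 300.0], labels=["I", "II"])
    assert pattern_divergence(sites, sites) == 0.0


def test_divergence_penalizes_unmatched_sites():
    a = [PreferentialSite("I", 100.0, 1.0, 4, ("MN-Rap1",), mean_percent=10.0)]
    b = []
    assert pattern_divergence(a, b) == pytest.approx(10.0)


def test_foldback_modes_differ_only_off_the_wt_chromosome():
    params = DigestionParams(n_molecules=1000, seed=21)
    direct = foldback_test("direct_binding", "sir", "chromosomal", params)
    folded = foldback_test("foldback", "sir", "chromosomal", params)
    assert direct.x_site_count >= 4
    assert folded.x_site_count <= direct.x_site_count - 4
    assert folded.divergence > direct.divergence


def test_foldback_direct_mode_keeps_x_sites_on_plasmid():
    params = DigestionParams(n_molecules=1000, seed=22)
    r = foldback_test("direct_binding", "WT", "plasmid", params)
    assert r.x_site_count >= 4
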