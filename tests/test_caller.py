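"""Band calling, end-labeling offsets and site consolidation."""

import numpy as np
import pytest

from telochec import caller, gel
from telochec.caller import (BandCall, SiteObservation, consolidate, detect_bands,
                             sizes_to_cut_offsets)
from telochec.chec_sim import DigestionParams, FragmentPopulation, LaneId, simulate_lane
from telochec.templates import build_template

CAL = gel.DEFAULT_CALIBRATION


def _pop(fragments):
    lane = LaneId("toy", "WT", "GBD-MN", 1.0, "30C")
    return FragmentPopulation(lane, np.asarray(fragments, float), len(fragments))


def test_single_gaussian_detected_at_center():
    profile = gel.render_lane(_pop([700.0] * 300))
    bands = detect_bands(profile, CAL)
    assert len(bands) == 1
    assert bands[0].size == pytest.approx(700.0, rel=0.02)


def test_two_bands_sized_within_two_percent():
    profile = gel.render_lane(_pop([500.0] * 200 + [800.0] * 150))
    bands = detect_bands(profile, CAL)
    assert len(bands) == 2
    assert bands[0].size == pytest.approx(500.0, rel=0.02)
    assert bands[1].size == pytest.approx(800.0, rel=0.02)


def test_flat_profile_yields_no_bands():
    profile = gel.LaneProfile(np.arange(0.0, 100.0, 0.25),
                              np.zeros(400), band_sigma=1.2)
    assert detect_bands(profile, CAL) == []


def test_uncut_band_excluded_in_time_zero_lane():
    t = build_template("TRP1ARS1")
    pop = simulate_lane(t, "GBD-MN", DigestionParams(n_molecules=500, seed=1), 0.0)
    profile = gel.render_lane(pop)
    bands = detect_bands(profile, CAL, exclude_size_above=0.97 * t.length)
    assert bands == []


def test_percent_signal_invariant_under_intensity_scaling():
    profile = gel.render_lane(_pop([400.0] * 100 + [900.0] * 300))
    scaled = gel.LaneProfile(profile.positions, profile.intensity * 7.5,
                             band_sigma=profile.band_sigma)
    b1 = detect_bands(profile, CAL)
    b2 = detect_bands(scaled, CAL)
    assert [round(b.percent_signal, 6) for b in b1] == [
        round(b.percent_signal, 6) for b in b2
    ]


def test_cut_offsets_equal_band_sizes_for_probe_anchored_fragments():
    t = build_template("TEL03L")
    bands = [BandCall(None, 0.0, 804.0, 5.0, 0.5)]
    assert sizes_to_cut_offsets(bands, t)[0] == pytest.approx(804.0)


def test_fragment_larger_than_template_rejected():
    t = build_template("TRP1ARS1")
    bands = [BandCall(None, 0.0, t.length + 100.0, 5.0, 0.5)]
    with pytest.raises(ValueError):
        sizes_to_cut_offsets(bands, t)


@pytest.mark.parametrize("q", [300.0, 700.0, 1200.0])
def test_single_planted_cut_round_trip(q):
    """Render -> detect -> size recovers a planted cut offset."""
    rng = np.random.default_rng(int(q))
    frags = np.concatenate([q + rng.uniform(-4, 4, 400), np.full(300, 2000.0)])
    profile = gel.render_lane(_pop(frags))
    bands = detect_bands(profile, CAL, exclude_size_above=1900.0)
    assert len(bands) == 1
    assert bands[0].size == pytest.approx(q, abs=0.02 * q)


def test_consolidate_mean_and_sd():
    sites = consolidate([500.0, 505.0, 498.0])
    assert len(sites) == 1
    assert sites[0].mean_offset == pytest.approx(501.0)
    assert sites[0].sd_offset == pytest.approx(np.std([500, 505, 498], ddof=1))
    assert sites[0].n_observations == 3


def test_consolidate_splits_distant_observations():
    sites = consolidate([500.0, 505.0, 900.0])
    assert len(sites) == 2
    assert sites[1].single_support


def test_consolidate_empty_input():
    assert consolidate([]) == []


def test_labels_follow_terminal_convention():
    obs = [SiteObservation(o, "GBD-MN") for o in (200.0, 600.0, 1000.0)]
    proximal = consolidate(obs, label_order="proximal_first")
    distal = consolidate(obs, label_order="distal_first")
    assert [s.label for s in proximal] == ["I", "II", "III"]
    assert [s.label for s in distal] == ["III", "II", "I"]  # I = telomere-proximal


def test_supporting_constructs_recorded():
    obs = [SiteObservation(500.0, "GBD-MN"), SiteObservation(503.0, "MN-Rap1")]
    (site,) = consolidate(obs)
    assert site.supporting_constructs == ("GBD-MN", "MN-Rap1")
    assert caller.is_common(site, ("GBD-MN",))
    assert not caller.is_common(site, ("GBD-MN", "NLS-MN"))


def test_diffuse_region_flagging():
    # two sharp bands with an elevated plateau between them
    profile = gel.render_lane(_pop([400.0] * 200 + [600.0] * 200))
    bands = detect_bands(profile, CAL)
    clean = caller.diffuse_regions(profile, bands, CAL)
    assert len(clean) == 1 and not clean[0]["diffuse"]
    lo = CAL.migration(600.0)
    hi = CAL.migration(400.0)
    plateau = ((profile.positions > lo) & (profile.positions < hi))
    raised = profile.intensity + plateau * 1.5 * profile.intensity.max()
    noisy = gel.LaneProfile(profile.positions, raised, band_sigma=profile.band_sigma)
    flagged = caller.diffuse_regions(noisy, detect_bands(noisy, CAL), CAL)
    assert any(r["diffuse"] for r in flagged)
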