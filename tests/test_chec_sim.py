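"""Forward digestion model: profiles, kinetics, conservation, invariance."""

import numpy as np
import pytest
from scipy import stats

from telochec import chec_sim, templates
from telochec.chec_sim import (DigestionParams, accessibility_profile,
                               concentration_profile, expected_cuts, get_construct,
                               simulate_experiment, simulate_lane)
from telochec.templates import (GenomicFeature, OccupantSpec, SubtelomereTemplate,
                                build_template)


def toy_template(name="toy", length=1600, n_nuc=8, linker=20, terminal=False):
    """Regular nucleosome array: 146-bp cores separated by open linkers."""
    occ, pos = [], 0
    for _ in range(n_nuc):
        occ.append(OccupantSpec("nucleosome", pos, pos + 146))
        pos += 146 + linker
    feats = [
        GenomicFeature("rs", "restriction_site", 0, 6),
        GenomicFeature("probe", "probe", 0, 80),
        GenomicFeature("rs2", "restriction_site", length - 6, length),
    ]
    return SubtelomereTemplate(
        name=name, length=length, anchor="X/left", features=tuple(feats),
        occupants=tuple(occ), probe=(0, 80), terminal=terminal,
        ground_truth_sites=(),
    )


def test_accessibility_profile_construction():
    t = toy_template()
    no_occ = SubtelomereTemplate(
        name="naked", length=500, anchor="X/left",
        features=(GenomicFeature("rs", "restriction_site", 0, 6),
                  GenomicFeature("p", "probe", 0, 50),
                  GenomicFeature("rs2", "restriction_site", 494, 500)),
        occupants=(), probe=(0, 50), terminal=False, ground_truth_sites=(),
    )
    assert np.all(accessibility_profile(no_occ) == 1.0)

    one = SubtelomereTemplate(
        name="one", length=500, anchor="X/left",
        features=no_occ.features,
        occupants=(OccupantSpec("nucleosome", 100, 246, protection=0.98),),
        probe=(0, 50), terminal=False, ground_truth_sites=(),
    )
    a = accessibility_profile(one)
    assert np.allclose(a[100:246], 0.02)
    assert np.allclose(a[:100], 1.0) and np.allclose(a[246:], 1.0)


def test_rap1_array_is_nearly_inaccessible():
    t = build_template("YpTRF")
    a = accessibility_profile(t)
    assert np.all(a[t.junction:] < 0.1)


def test_free_construct_concentration_is_flat():
    t = build_template("TEL03L")
    for name in chec_sim.FREE_CONSTRUCTS:
        assert np.all(concentration_profile(t, get_construct(name)) == 1.0)


def test_box_kernel_concentration_by_construction():
    t = build_template("YpTRF")
    con = get_construct("MN-Rap1")
    c = concentration_profile(t, con)
    (tg,) = t.features_of("TG_tract")
    center = tg.center
    inside = int(center)  # tract midpoint
    outside = int(center - con.reach - 50)
    assert c[inside] == pytest.approx(1.0 + con.enhancement)
    assert c[outside] == 1.0


def test_mn_rap1_enhanced_over_internal_x_element():
    """Direct Rap1 binding concentrates MN-Rap1 over the X element."""
    t = build_template("X05R_AF")
    c = concentration_profile(t, get_construct("MN-Rap1"))
    for f in t.features_of("Rap1_site"):
        assert c[int(f.center)] > 1.0


def test_time_zero_yields_full_length_fragments():
    t = build_template("TRP1ARS1")
    pop = simulate_lane(t, "GBD-MN", DigestionParams(n_molecules=200, seed=1), 0.0)
    assert np.all(pop.fragments == t.length)
    t2 = build_template("YpTRF")
    pop2 = simulate_lane(t2, "GBD-MN", DigestionParams(n_molecules=200, seed=1), 0.0)
    assert np.all(pop2.fragments == pop2.full_lengths)
    assert np.all(pop2.fragments >= t2.core_length)


def test_undeclared_time_rejected():
    t = build_template("TRP1ARS1")
    with pytest.raises(ValueError, match="time"):
        simulate_lane(t, "GBD-MN", DigestionParams(seed=1), 3.25)


def test_mass_conservation_per_molecule():
    t = toy_template()
    pop = simulate_lane(t, "GBD-MN", DigestionParams(n_molecules=300, seed=5),
                        5.0, keep_all=True)
    for i, frags in enumerate(pop.all_fragments):
        assert np.isclose(frags.sum(), pop.full_lengths[i])
        assert np.all(frags > 0)


def test_poisson_mean_cuts_matches_closed_form():
    t = toy_template()
    params = DigestionParams(n_molecules=2000, seed=9)
    pop = simulate_lane(t, "GBD-MN", params, 2.0, keep_all=True)
    n_cuts = np.array([f.size - 1 for f in pop.all_fragments])
    expected = expected_cuts(t, "GBD-MN", params, 2.0)
    se = np.sqrt(expected / params.n_molecules)
    assert abs(n_cuts.mean() - expected) < 3 * se


def test_mean_detected_length_nonincreasing_in_time():
    t = build_template("TEL03L")
    params = DigestionParams(n_molecules=2000, seed=2)
    means = [simulate_lane(t, "NLS-MN", params, tt).fragments.mean()
             for tt in (0.0, 1.0, 2.0, 5.0)]
    assert all(a >= b - 5.0 for a, b in zip(means, means[1:]))


def test_temperature_slows_digestion():
    t = build_template("TEL03L")
    params = DigestionParams(n_molecules=1500, seed=4)
    warm = simulate_lane(t, "NLS-MN", params, 5.0, "30C").fragments.mean()
    cold = simulate_lane(t, "NLS-MN", params, 5.0, "4C").fragments.mean()
    assert cold > warm


def test_lane_reproducibility_and_seed_sensitivity():
    t = build_template("TEL06R")
    params = DigestionParams(n_molecules=400, seed=3)
    a = simulate_lane(t, "MN-Rap1", params, 2.0)
    b = simulate_lane(t, "MN-Rap1", params, 2.0)
    assert np.array_equal(a.fragments, b.fragments)
    c = simulate_lane(t, "MN-Rap1", DigestionParams(n_molecules=400, seed=8), 2.0)
    assert not np.array_equal(a.fragments, c.fragments)


def test_free_constructs_statistically_exchangeable():
    """GBD-MN and NLS-MN lanes are exchangeable: KS does not reject at 1%."""
    t = build_template("YpTRF")
    rejections = 0
    for seed in range(10):
        params = DigestionParams(n_molecules=800, seed=100 + seed)
        g = simulate_lane(t, "GBD-MN", params, 2.0).fragments
        n = simulate_lane(t, "NLS-MN", params, 2.0).fragments
        if stats.ks_2samp(g, n).pvalue < 0.01:
            rejections += 1
    assert rejections <= 1


def test_genotype_invariance_of_direct_binding_patterns():
    """sir / yku deletions leave free and MN-Rap1 digestion patterns unchanged."""
    rejections = 0
    for construct in ("NLS-MN", "MN-Rap1"):
        for seed in range(10):
            frags = {}
            for genotype in ("WT", "sir"):
                t = build_template("TEL06R", genotype=genotype)
                params = DigestionParams(n_molecules=800, seed=500 + seed)
                frags[genotype] = simulate_lane(t, construct, params, 2.0).fragments
            if stats.ks_2samp(frags["WT"], frags["sir"]).pvalue < 0.01:
                rejections += 1
    assert rejections <= 2


def test_experiment_cardinality():
    t = build_template("TRP1ARS1")
    params = DigestionParams(n_molecules=50, seed=1)
    schedule = ((1.0, "30C"), (2.0, "30C"), (5.0, "30C"))
    lanes = simulate_experiment(t, ["GBD-MN", "NLS-MN", "MN-Rap1", "H2A-MN"],
                                params, schedule)
    assert len(lanes) == 12


def test_complete_h2a_digestion_yields_mononucleosome_mode():
    """Late H2A-MN digestion of a regular array: modal detected fragment
    approximates the nucleosome repeat length."""
    t = toy_template(linker=20)
    params = DigestionParams(n_molecules=3000, seed=6)
    pop = simulate_lane(t, "H2A-MN", params, 5.0, "30C")
    cut = pop.fragments[pop.fragments < t.length]
    hist, edges = np.histogram(cut, bins=np.arange(0, 800, 20))
    mode = 0.5 * (edges[hist.argmax()] + edges[hist.argmax() + 1])
    repeat = 146 + 20
    assert abs(mode - repeat) < 0.25 * repeat


def test_junction_band_dominates_early_mn_rap1_time_course():
    """The subtelomere-telomere junction cut is the main early MN-Rap1 product."""
    t = build_template("YpTRF")
    params = DigestionParams(n_molecules=4000, seed=12)
    # earliest informative (very partial) digestion point
    pop = simulate_lane(t, "MN-Rap1", params, 2.0, "4C")
    cut = pop.fragments[pop.fragments < t.core_length]
    junction_band = ((cut > 870) & (cut < 910)).sum()
    # compare against any other 40-bp window of sub-full-length signal
    other = max(((cut > lo) & (cut < lo + 40)).sum() for lo in range(100, 820, 40))
    assert junction_band > other


def test_construct_enhancement_validation():
    with pytest.raises(ValueError):
        chec_sim.MNConstruct("bad", "free", enhancement=2.0)
    with pytest.raises(ValueError):
        chec_sim.MNConstruct("bad", "site", enhancement=0.0)
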