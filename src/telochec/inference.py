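"""Interpretive layer: interval classification, accessibility ratios,
chromatin-model reconstruction and the cis-fold-back discrimination test.

The central rule is the 146-bp nucleosome classifier: an inter-site spacing
of at least 146 bp (the minimal nucleosome footprint) is compatible with a
positioned nucleosome; anything shorter must be held by a non-histone
occupant (ORC on an ACS, Abf1, or a Tbf1/Reb1 array near the junction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import caller, chec_sim, gel, templates
from .caller import PreferentialSite, SiteObservation

NUCLEOSOME_THRESHOLD = 146.0
ASSOCIATION_MARGIN = 10.0  # a feature center must sit this far inside the interval


@dataclass(frozen=True)
class IntervalCall:
    left_label: str
    right_label: str
    spacing_mean: float
    spacing_sd: float
    klass: str  # nucleosome_compatible | sub_nucleosomal
    association: str  # ORC_ACS | Abf1 | Tbf1_Reb1_array | TG_junction | unassigned
    left_offset: float = 0.0
    right_offset: float = 0.0


@dataclass(frozen=True)
class AccessibilityRatio:
    template: str
    construct: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...]
    value: float | None  # None when below the detection limit
    sd: float = 0.0
    n_lanes: int = 0
    below_detection: bool = False


@dataclass(frozen=True)
class ChromatinModel:
    template: str
    occupants: tuple  # ((left_offset, right_offset, kind), ...)
    terminal_nfr: bool
    orc_site: bool
    abf1_site: bool


#: template -> (numerator band labels, denominator band labels) of the
#: junction accessibility ratio (distal_first labeling convention)
RATIO_SPECS = {
    "YpTRF": (("I",), ("II", "III")),
    "TEL03L": (("I",), ("V", "VI")),
    "TEL06R": (("I",), ("III",)),
}


def classify_intervals(
    sites: list[PreferentialSite],
    template: templates.SubtelomereTemplate | None = None,
    threshold: float = NUCLEOSOME_THRESHOLD,
) -> list[IntervalCall]:
    """Classify consecutive inter-site intervals with the 146-bp rule.

    Spacing SDs of the flanking sites propagate in quadrature.  A spacing of
    exactly 146 bp counts as nucleosome_compatible (146 bp is the stated
    minimum).  Associations are assigned from template features whose center
    lies at least ``ASSOCIATION_MARGIN`` bp inside the interval, with
    precedence ORC_ACS > Abf1 > Tbf1_Reb1_array.
    """
    ordered = sorted(sites, key=lambda s: s.mean_offset)
    if len(ordered) < 2:
        return []
    out = []
    junction = template.junction if template is not None else None
    most_distal_left = ordered[-2].mean_offset
    for left, right in zip(ordered, ordered[1:]):
        spacing = right.mean_offset - left.mean_offset
        sd = float(np.hypot(left.sd_offset, right.sd_offset))
        klass = "sub_nucleosomal" if spacing < threshold else "nucleosome_compatible"
        association = "unassigned"
        if template is not None:
            lo = left.mean_offset + ASSOCIATION_MARGIN
            hi = right.mean_offset - ASSOCIATION_MARGIN
            inside = [f for f in template.features if lo <= f.center <= hi]
            kinds = [f.kind for f in inside]
            n_grf = sum(k in ("Tbf1_site", "Reb1_site") for k in kinds)
            if "ACS" in kinds:
                association = "ORC_ACS"
            elif "Abf1_site" in kinds:
                association = "Abf1"
            elif n_grf >= 2:
                association = "Tbf1_Reb1_array"
            elif (
                template.terminal
                and junction is not None
                and left.mean_offset == most_distal_left
                and junction - right.mean_offset <= 50
            ):
                association = "TG_junction"
        out.append(
            IntervalCall(
                left_label=left.label,
                right_label=right.label,
                spacing_mean=float(spacing),
                spacing_sd=sd,
                klass=klass,
                association=association,
                left_offset=left.mean_offset,
                right_offset=right.mean_offset,
            )
        )
    return out


def _percent_by_label(bands, sites, tolerance: float = caller.DEFAULT_CLUSTER_TOLERANCE):
    """Sum per-lane percent_signal of bands matched to consolidated sites."""
    totals: dict[str, float] = {}
    for b in bands:
        best, dist = None, tolerance
        for s in sites:
            d = abs(b.size - s.mean_offset)
            if d <= dist:
                best, dist = s.label, d
        if best is not None:
            totals[best] = totals.get(best, 0.0) + b.percent_signal
    return totals


def accessibility_ratio(
    lane_bands: dict,
    sites: list[PreferentialSite],
    template: templates.SubtelomereTemplate,
    construct: str,
    detection_limit: float = 0.5,
) -> AccessibilityRatio:
    """Junction/ACS cleavage ratio for one construct, averaged over lanes.

    ``lane_bands`` maps lane ids to their band calls; lanes of other
    constructs are ignored.  A lane whose denominator signal falls below
    ``detection_limit`` percent is excluded; if no lane has measurable
    denominator the ratio is flagged below_detection (the "DL" case).
    """
    if template.name not in RATIO_SPECS:
        raise ValueError(f"no ratio defined for template {template.name}")
    num_labels, den_labels = RATIO_SPECS[template.name]
    values = []
    for lane, bands in lane_bands.items():
        if getattr(lane, "construct", None) != construct:
            continue
        pct = _percent_by_label(bands, sites)
        den = sum(pct.get(l, 0.0) for l in den_labels)
        if den < detection_limit:
            continue
        num = sum(pct.get(l, 0.0) for l in num_labels)
        values.append(num / den)
    if not values:
        return AccessibilityRatio(template.name, construct, num_labels, den_labels,
                                  value=None, below_detection=True)
    arr = np.array(values)
    return AccessibilityRatio(
        template.name, construct, num_labels, den_labels,
        value=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        n_lanes=int(arr.size),
    )


def reconstruct_model(
    intervals: list[IntervalCall],
    template: templates.SubtelomereTemplate,
) -> ChromatinModel:
    """Map classified intervals onto an occupant reconstruction.

    nucleosome_compatible -> nucleosome; sub_nucleosomal with an ACS ->
    ORC; with an Abf1 site -> Abf1; the junction-proximal interval of a
    terminal fragment with a Tbf1/Reb1 array -> GRF-bound NFR.  The
    terminal-NFR flag records that no nucleosome abuts the TG repeats.
    """
    occ = []
    ordered = sorted(intervals, key=lambda iv: iv.left_offset)
    for k, iv in enumerate(ordered):
        junction_proximal = template.terminal and k == len(ordered) - 1
        if junction_proximal and iv.association in ("Tbf1_Reb1_array", "TG_junction"):
            kind = "GRF_NFR"
        elif iv.klass == "nucleosome_compatible":
            kind = "nucleosome"
        elif iv.association == "ORC_ACS":
            kind = "ORC"
        elif iv.association == "Abf1":
            kind = "Abf1"
        elif iv.association == "Tbf1_Reb1_array":
            kind = "GRF_NFR"
        else:
            kind = "unassigned"
        occ.append((iv.left_offset, iv.right_offset, kind))
    terminal_nfr = bool(
        template.terminal and occ and occ[-1][2] != "nucleosome"
    )
    return ChromatinModel(
        template=template.name,
        occupants=tuple(occ),
        terminal_nfr=terminal_nfr,
        orc_site=any(k == "ORC" for *_, k in occ)
        or any(iv.association == "ORC_ACS" for iv in intervals),
        abf1_site=any(k == "Abf1" for *_, k in occ)
        or any(iv.association == "Abf1" for iv in intervals),
    )


# ---------------------------------------------------------------------------
# cis-fold-back discrimination
# ---------------------------------------------------------------------------


@dataclass
class FoldbackResult:
    mode: str
    genotype: str
    context: str
    sites: list[PreferentialSite]  # offsets relative to the X-element start
    x_site_count: int
    divergence: float


def _mn_rap1_for_mode(mode: str, genotype: str, context: str) -> chec_sim.MNConstruct:
    base = chec_sim.get_construct("MN-Rap1")
    if mode == "direct_binding":
        return base  # Rap1 binds the X element directly, everywhere
    if mode == "foldback":
        # enhancement over the X element requires SIR/yKu-dependent delivery
        # of terminal Rap1 in cis: only the WT chromosomal locus has it
        if genotype == "WT" and context == "chromosomal":
            return base
        from dataclasses import replace

        return replace(base, anchor_kinds=("TG_tract",))
    raise ValueError(f"unknown mode {mode!r}")


def _x_window(template: templates.SubtelomereTemplate) -> tuple[float, float]:
    bounds = {f.name: f.center for f in template.features_of("element_boundary")}
    return bounds["X_start"], bounds["XY_junction"]


#: lanes used for fold-back discrimination: very partial on-ice digestion,
#: where tether-enhanced cutting is detectable but free-level cutting of the
#: same linkers stays below the band-calling threshold
FOLDBACK_LANES = ((1.0, "4C"),)
FOLDBACK_PROMINENCE = 0.1


def _mn_rap1_sites(
    template: templates.SubtelomereTemplate,
    construct: chec_sim.MNConstruct,
    params: chec_sim.DigestionParams,
    lanes=FOLDBACK_LANES,
    min_prominence: float = FOLDBACK_PROMINENCE,
) -> list[PreferentialSite]:
    calibration = gel.DEFAULT_CALIBRATION
    x_start, _ = _x_window(template)
    observations = []
    for t, temp in lanes:
        pop = chec_sim.simulate_lane(template, construct, params, t, temp)
        profile = gel.render_lane(pop, calibration)
        bands = caller.detect_bands(
            profile, calibration, min_prominence,
            exclude_size_above=0.97 * template.length,
        )
        for b in bands:
            observations.append(
                SiteObservation(b.size - x_start, construct.name, pop.lane,
                                b.percent_signal)
            )
    return caller.consolidate(observations, template=template.name)


def pattern_divergence(sites_a, sites_b, tolerance: float = 25.0) -> float:
    """Matched-band L1 distance between two consolidated site patterns.

    Sites within ``tolerance`` bp are matched (nearest first) and contribute
    |delta percent_signal|; unmatched sites contribute their full percent.
    Identical patterns give 0.
    """
    a = sorted(sites_a, key=lambda s: s.mean_offset)
    b = list(sorted(sites_b, key=lambda s: s.mean_offset))
    div = 0.0
    used = set()
    for s in a:
        best_j, best_d = None, tolerance
        for j, t in enumerate(b):
            if j in used:
                continue
            d = abs(s.mean_offset - t.mean_offset)
            if d <= best_d:
                best_j, best_d = j, d
        if best_j is None:
            div += s.mean_percent
        else:
            used.add(best_j)
            div += abs(s.mean_percent - b[best_j].mean_percent)
    for j, t in enumerate(b):
        if j not in used:
            div += t.mean_percent
    return float(div)


def foldback_test(
    mode: str,
    genotype: str = "WT",
    context: str = "chromosomal",
    params: chec_sim.DigestionParams | None = None,
    reference_sites: list[PreferentialSite] | None = None,
) -> FoldbackResult:
    """MN-Rap1 ChEC on the TEL05R X-Y' junction under a fold-back hypothesis.

    ``mode="direct_binding"`` anchors MN-Rap1 enhancement at the X-element
    Rap1 sites in every genotype and context; ``mode="foldback"`` grants the
    X-element enhancement only to the WT chromosomal locus (SIR/yKu-delivered
    terminal Rap1), leaving only TG-tract anchoring otherwise -- and the
    analyzed fragments carry no TG tract.  Site offsets are reported
    relative to the X-element start so chromosomal and plasmid patterns are
    comparable; the divergence is the matched-band L1 distance against the
    WT-chromosomal reference pattern of the same mode.
    """
    if context not in ("chromosomal", "plasmid"):
        raise ValueError(f"unknown context {context!r}")
    params = params or chec_sim.DigestionParams()
    tmpl_name = "X05R_AF" if context == "chromosomal" else "p05RA"
    template = templates.build_template(tmpl_name, genotype=genotype)
    construct = _mn_rap1_for_mode(mode, genotype, context)
    sites = _mn_rap1_sites(template, construct, params)

    if reference_sites is None:
        ref_template = templates.build_template("X05R_AF", genotype="WT")
        ref_params = chec_sim.DigestionParams(
            n_molecules=params.n_molecules,
            time_points=params.time_points,
            base_rate=params.base_rate,
            seed=chec_sim.derive_seed(params.seed, "foldback-reference"),
        )
        reference_sites = _mn_rap1_sites(
            ref_template, _mn_rap1_for_mode(mode, "WT", "chromosomal"), ref_params
        )

    x_start, junction = _x_window(template)
    lo, hi = 0.0, junction - x_start
    n_x = sum(1 for s in sites if lo - 25 <= s.mean_offset <= hi + 25)
    return FoldbackResult(
        mode=mode,
        genotype=genotype,
        context=context,
        sites=sites,
        x_site_count=int(n_x),
        divergence=pattern_divergence(sites, reference_sites),
    )
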