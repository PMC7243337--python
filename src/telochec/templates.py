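"""Coordinate-annotated subtelomere/telomere templates with ground-truth occupancy.

Each template describes one restriction fragment analyzed by indirect
end-labeling: offsets are 0-based bp measured from the probe-proximal
restriction cut and increase toward the telomere (or distal) end; intervals
are half-open.  A template carries three layers:

* ``features`` -- printed or reconstructed sequence annotations (restriction
  sites, the probe, ACS, GRF motifs, the TG tract, element boundaries);
* ``occupants`` -- the ground-truth protein occupancy used by the forward
  ChEC simulator (nucleosomes, ORC, GRFs, the Rap1-covered tract);
* ``ground_truth_sites`` -- the accessible linker centers the occupancy
  plants, i.e. where preferential MNase cutting is expected.

Coordinates quoted in the literature (e.g. the TEL03L Abf1 site centered at
783 bp from the HindIII cut, or the X(TEL05R) ACS at 1325 bp from the PvuI
cut) are tagged ``source="paper_printed"``; offsets only ever shown
graphically are chained from printed spacings and tagged
``source="reconstructed"``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

FEATURE_KINDS = frozenset(
    {
        "restriction_site",
        "probe",
        "ACS",
        "Abf1_site",
        "Tbf1_site",
        "Reb1_site",
        "Rap1_site",
        "TG_tract",
        "element_boundary",
    }
)

# "unknown" covers protected spans whose occupant the source data leave open
# (the ACS-adjacent short fragments may be ORC plus an unidentified factor).
OCCUPANT_PROTEINS = frozenset(
    {"nucleosome", "ORC", "Abf1", "Tbf1", "Reb1", "Rap1_array", "Yku", "unknown"}
)

NUCLEOSOME_FOOTPRINT = 146
ORC_FOOTPRINT_RANGE = (38, 44)

#: default suppression of the cut rate inside a footprint, by occupant kind.
#: Values are high because the modeled blots show sharp preferential bands
#: with virtually no background cutting inside protected regions.
DEFAULT_PROTECTION = {
    "nucleosome": 0.997,
    "ORC": 0.98,
    "Abf1": 0.98,
    "Tbf1": 0.98,
    "Reb1": 0.98,
    "unknown": 0.99,
    "Rap1_array": 0.995,
    "Yku": 0.98,
}

TEMPLATE_NAMES = (
    "YpTRF",
    "TEL03L",
    "TEL06R",
    "X05R_AF",
    "X16R_AF",
    "TRP1ARS1",
    "p05RA",
)

GENOTYPES = ("WT", "sir", "yku")


@dataclass(frozen=True)
class GenomicFeature:
    """A named interval on a template, offsets relative to the anchor cut."""

    name: str
    kind: str
    start: int
    end: int
    source: str = "reconstructed"  # paper_printed | reconstructed | pwm_predicted
    citation: str | None = None

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end}) for {self.name}")
        if self.source == "paper_printed" and not self.citation:
            raise ValueError(f"paper_printed feature {self.name} needs a citation")

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class OccupantSpec:
    """Ground-truth protein footprint suppressing MNase cutting."""

    protein: str
    start: int
    end: int
    protection: float | None = None  # None -> kind default

    def __post_init__(self):
        if self.protein not in OCCUPANT_PROTEINS:
            raise ValueError(f"unknown occupant protein {self.protein!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad footprint [{self.start}, {self.end})")
        if self.protein == "nucleosome" and self.end - self.start != NUCLEOSOME_FOOTPRINT:
            raise ValueError("nucleosome footprint must be 146 bp")
        if self.protein == "ORC":
            lo, hi = ORC_FOOTPRINT_RANGE
            if not lo <= self.end - self.start <= hi:
                raise ValueError("ORC footprint must be 38-44 bp")
        p = self.effective_protection
        if not 0.0 <= p <= 1.0:
            raise ValueError("protection must lie in [0, 1]")

    @property
    def effective_protection(self) -> float:
        if self.protection is not None:
            return self.protection
        return DEFAULT_PROTECTION[self.protein]

    @property
    def footprint(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class GroundTruthSite:
    """A planted preferential cut site (accessible linker center)."""

    label: str
    offset: float
    accessibility: float = 1.0  # 1 - protection of the linker, if partially shielded
    note: str = ""


@dataclass(frozen=True)
class SubtelomereTemplate:
    name: str
    length: int
    anchor: str  # e.g. "XhoI/left": enzyme + side carrying the probe
    features: tuple[GenomicFeature, ...]
    occupants: tuple[OccupantSpec, ...]
    probe: tuple[int, int]
    terminal: bool
    ground_truth_sites: tuple[GroundTruthSite, ...]
    tg_length_model: tuple[float, float] | None = None  # (mean, sd), terminal only
    junction: int | None = None  # TG-tract start (terminal) or X-Y' boundary
    label_order: str = "proximal_first"  # or "distal_first" (terminal TRF convention)
    genotype: str = "WT"
    variant: str = ""

    def __post_init__(self):
        validate_template(self)

    # -- convenience accessors -------------------------------------------------
    def features_of(self, kind: str) -> list[GenomicFeature]:
        return [f for f in self.features if f.kind == kind]

    @property
    def core_length(self) -> int:
        """Length up to the TG-tract start (terminal) or full length."""
        return self.junction if (self.terminal and self.junction) else self.length

    def spacings(self) -> list[float]:
        """Center-to-center spacings between consecutive planted sites."""
        offs = sorted(s.offset for s in self.ground_truth_sites)
        return [b - a for a, b in zip(offs, offs[1:])]


def validate_template(t: SubtelomereTemplate) -> None:
    # note: arbitrary names are allowed so callers can define ad-hoc
    # templates; build_template() restricts itself to TEMPLATE_NAMES
    p0, p1 = t.probe
    if not 0 <= p0 < p1 <= t.length:
        raise ValueError("probe interval outside template")
    for f in t.features:
        if f.end > t.length:
            raise ValueError(f"feature {f.name} exceeds template length")
    occ = sorted(t.occupants, key=lambda o: o.start)
    for a, b in zip(occ, occ[1:]):
        if b.start < a.end:
            raise ValueError(
                f"occupant footprints overlap: {a.protein}{a.footprint} / {b.protein}{b.footprint}"
            )
    if occ and occ[-1].end > t.length:
        raise ValueError("occupant exceeds template length")
    tg = t.features_of("TG_tract")
    if t.terminal:
        if t.tg_length_model is None:
            raise ValueError("terminal template requires tg_length_model")
        if len(tg) != 1:
            raise ValueError("terminal template must have exactly one TG_tract")
        if tg[0].end != t.length:
            raise ValueError("TG_tract must abut the telomeric end")
    else:
        if t.tg_length_model is not None:
            raise ValueError("tg_length_model only valid on terminal templates")
        n_rs = len(t.features_of("restriction_site"))
        if n_rs < 2:
            raise ValueError("non-terminal template needs a closing restriction_site")


# ---------------------------------------------------------------------------
# Template construction
# ---------------------------------------------------------------------------

_TG_MODEL = (300.0, 75.0)  # mean +/- SD of the terminal repeat tract, bp
TG_TRUNCATION = (150.0, 525.0)  # +/- 2 SD


def _nuc(a, b, protection=None):
    return OccupantSpec("nucleosome", a, b, protection)


def _occ(kind, a, b, protection=None):
    return OccupantSpec(kind, a, b, protection)


def _build_yptrf(genotype: str, variant: str) -> SubtelomereTemplate:
    # Y' terminal restriction fragment, XhoI anchor, YPX probe beside the cut.
    # Printed spacings: II-III 106, III-IV 129; I-II ~200 (the GRF-held region);
    # site I is the junction cut, dominant in MN-Rap1 lanes.
    junction = 896
    length = junction + int(_TG_MODEL[0])
    acs_occ_flanks = variant != "orc_alone"
    occupants = [
        _nuc(0, 146),
        _nuc(146, 292),
        # site V linker [292, 304)
        _nuc(304, 450),
        # site IV linker [450, 461)
        _occ("unknown", 461, 578),  # III-IV protected span (129-bp class)
        # site III linker [578, 590)
        *([_occ("unknown", 590, 616)] if acs_occ_flanks else []),
        _occ("ORC", 616, 657),  # centered on the Y'-ACS
        *([_occ("unknown", 657, 684)] if acs_occ_flanks else []),
        # site II linker [684, 696)
        _occ("Tbf1", 696, 760),
        _occ("Reb1", 760, 822),
        _occ("Tbf1", 822, 884),
        # site I: junction linker, partially shielded from free MNase
        _occ("unknown", 884, 896, protection=0.8),
        _occ("Rap1_array", 896, length),
    ]
    features = [
        GenomicFeature("XhoI", "restriction_site", 0, 6,
                       "paper_printed", "conserved Y' XhoI site"),
        GenomicFeature("YPX_probe", "probe", 0, 100,
                       "paper_printed", "Y'-specific probe proximal to XhoI"),
        GenomicFeature("Yp_ACS", "ACS", 628, 645, "reconstructed"),
        GenomicFeature("Tbf1_a", "Tbf1_site", 722, 735),
        GenomicFeature("Tbf1_b", "Tbf1_site", 745, 758),
        GenomicFeature("Tbf1_c", "Tbf1_site", 800, 813),
        GenomicFeature("Tbf1_d", "Tbf1_site", 826, 839),
        # two Reb1 sites spaced 137 bp, surrounded by the Tbf1 sites
        GenomicFeature("Reb1_a", "Reb1_site", 711, 719),
        GenomicFeature("Reb1_b", "Reb1_site", 848, 856),
        GenomicFeature("TG", "TG_tract", junction, length,
                       "paper_printed", "300 +/- 75 bp heterogeneous telomeric repeats"),
    ]
    sites = [
        GroundTruthSite("V", 298.0),
        GroundTruthSite("IV", 455.5),
        GroundTruthSite("III", 584.0),
        GroundTruthSite("II", 690.0),
        GroundTruthSite("I", 890.0, accessibility=0.2,
                        note="junction cut; efficient only with tethered MN-Rap1"),
    ]
    return SubtelomereTemplate(
        name="YpTRF", length=length, anchor="XhoI/left",
        features=tuple(features), occupants=tuple(occupants), probe=(0, 100),
        terminal=True, tg_length_model=_TG_MODEL, junction=junction,
        label_order="distal_first", ground_truth_sites=tuple(sites),
        genotype=genotype, variant=variant or "orc_plus_unknown",
    )


def _build_tel03l(genotype: str, variant: str) -> SubtelomereTemplate:
    # X-only telomere, HindIII anchor.  Printed: site IV 804 +/- 21, Abf1 783,
    # spacings II-III 152, III-IV 187, V-VI 87, I-II ~106; ACS-Abf1 221 +/- 1;
    # site I 15.2 bp from the TG start.  Site II is shielded in WT and opens in
    # sir / yku mutants (encoded as a genotype toggle on its linker occupant).
    junction = 1264
    length = junction + int(_TG_MODEL[0])
    site2_shielded = genotype == "WT"
    occupants = [
        _nuc(0, 146),
        _occ("unknown", 146, 196),
        # VIII [196, 208)
        _nuc(208, 354),
        # VII [354, 366)
        _nuc(366, 512),
        # VI [512, 524)
        _occ("unknown", 524, 542),
        _occ("ORC", 542, 583),  # centered 562.5 = Abf1 783 - 220.5
        _occ("unknown", 583, 599),
        # V [599, 611)
        _nuc(611, 757),
        _occ("unknown", 757, 770),
        _occ("Abf1", 770, 798),
        # IV [798, 810)
        _nuc(810, 956),
        _occ("unknown", 956, 988),
        # III [988, 994)
        _nuc(994, 1140),
        # II [1140, 1152): weakly accessible in WT, open in sir/yku cells
        *([_occ("unknown", 1140, 1152, protection=0.7)] if site2_shielded else []),
        _occ("Tbf1", 1152, 1200),
        _occ("Reb1", 1200, 1243),
        # I [1243, 1255): junction cut, shielded from free MNase
        _occ("unknown", 1243, 1255, protection=0.8),
        _occ("Tbf1", 1255, 1264),
        _occ("Rap1_array", junction, length),
    ]
    features = [
        GenomicFeature("HindIII", "restriction_site", 0, 6,
                       "paper_printed", "fragment sizes plotted wrt the HindIII site"),
        GenomicFeature("probe", "probe", 0, 100,
                       "paper_printed", "TEL03L-specific probe"),
        GenomicFeature("X_start", "element_boundary", 240, 241),
        GenomicFeature("X03L_ACS", "ACS", 554, 571, "reconstructed"),
        GenomicFeature("Abf1", "Abf1_site", 776, 790,
                       "paper_printed", "Abf1 site centered at 783 bp from the HindIII site"),
        GenomicFeature("Reb1_distal", "Reb1_site", 1050, 1058),
        GenomicFeature("Tbf1_distal", "Tbf1_site", 1085, 1098),
        GenomicFeature("Tbf1_a", "Tbf1_site", 1156, 1169),
        GenomicFeature("Tbf1_b", "Tbf1_site", 1175, 1188),
        GenomicFeature("Reb1_a", "Reb1_site", 1205, 1213),
        GenomicFeature("Reb1_b", "Reb1_site", 1228, 1236),
        GenomicFeature("TG", "TG_tract", junction, length,
                       "paper_printed", "300 +/- 75 bp heterogeneous telomeric repeats"),
    ]
    sites = [
        GroundTruthSite("VIII", 202.0),
        GroundTruthSite("VII", 360.0),
        GroundTruthSite("VI", 518.0),
        GroundTruthSite("V", 605.0),
        GroundTruthSite("IV", 804.0, note="Abf1-adjacent; printed 804 +/- 21"),
        GroundTruthSite("III", 991.0),
        GroundTruthSite("II", 1146.0,
                        accessibility=0.3 if site2_shielded else 1.0,
                        note="H2A-MN only in WT; opens in sir/yku cells"),
        GroundTruthSite("I", 1249.0, accessibility=0.2,
                        note="junction cut, 15 bp from the TG start"),
    ]
    return SubtelomereTemplate(
        name="TEL03L", length=length, anchor="HindIII/left",
        features=tuple(features), occupants=tuple(occupants), probe=(0, 100),
        terminal=True, tg_length_model=_TG_MODEL, junction=junction,
        label_order="distal_first", ground_truth_sites=tuple(sites),
        genotype=genotype, variant=variant,
    )


def _build_tel06r(genotype: str, variant: str) -> SubtelomereTemplate:
    # X-only telomere lacking the dense distal Tbf1/Reb1 stretch; XhoI anchor.
    # Printed: I-II 143 +/- 9; site I 26 bp from the TG start; the two
    # ACS-flanking cuts are nearly unresolvable, encoded as a single accessible
    # flank on the distal side of ORC (site III).  The junction region is bound
    # by one Reb1 and one Abf1 and is markedly more accessible than on TEL03L.
    junction = 1000
    length = junction + int(_TG_MODEL[0])
    occupants = [
        _nuc(0, 146),
        _occ("unknown", 146, 269),
        # V [269, 281)
        _nuc(281, 427),
        _occ("unknown", 427, 434),
        # IV [434, 446)
        _nuc(446, 592),
        _occ("unknown", 592, 623),
        _occ("ORC", 623, 664),
        # III [664, 676): single resolvable ACS flank
        _occ("unknown", 676, 679),
        _nuc(679, 825),
        # II [825, 837)
        _occ("Abf1", 837, 901),
        _occ("Reb1", 901, 968),
        # I [968, 980): junction cut, moderately accessible even to free MN
        _occ("unknown", 968, 980, protection=0.5),
        _occ("Reb1", 980, 1000),
        _occ("Rap1_array", junction, length),
    ]
    features = [
        GenomicFeature("XhoI", "restriction_site", 0, 6,
                       "paper_printed", "fragment sizes plotted wrt the XhoI site"),
        GenomicFeature("probe", "probe", 0, 100,
                       "paper_printed", "TEL06R-specific probe"),
        GenomicFeature("X_start", "element_boundary", 250, 251),
        GenomicFeature("X06R_ACS", "ACS", 635, 652, "reconstructed"),
        GenomicFeature("Abf1", "Abf1_site", 857, 871, "reconstructed"),
        GenomicFeature("Reb1_a", "Reb1_site", 930, 938),
        GenomicFeature("Reb1_b", "Reb1_site", 984, 992),
        GenomicFeature("TG", "TG_tract", junction, length,
                       "paper_printed", "300 +/- 75 bp heterogeneous telomeric repeats"),
    ]
    sites = [
        GroundTruthSite("V", 275.0),
        GroundTruthSite("IV", 440.0),
        GroundTruthSite("III", 670.0, note="ACS-adjacent cut, ratio denominator"),
        GroundTruthSite("II", 831.0),
        GroundTruthSite("I", 974.0, accessibility=0.5,
                        note="junction cut, 26 bp from the TG start; accessible"),
    ]
    return SubtelomereTemplate(
        name="TEL06R", length=length, anchor="XhoI/left",
        features=tuple(features), occupants=tuple(occupants), probe=(0, 100),
        terminal=True, tg_length_model=_TG_MODEL, junction=junction,
        label_order="distal_first", ground_truth_sites=tuple(sites),
        genotype=genotype, variant=variant,
    )


def _x05r_layout(shift: int):
    """Shared X-element layout of the TEL05R X-Y' junction.

    ``shift`` maps genomic offsets (PvuI anchor, X start at 1281) onto the
    plasmid coordinate system (PstI anchor, X start at 1058).
    """
    s = shift
    occupants = [
        # X-I [1277, 1289)+s
        _occ("unknown", 1289 + s, 1304 + s),
        _occ("ORC", 1304 + s, 1345 + s),  # centered on the ACS at 1324.5
        _occ("unknown", 1345 + s, 1362 + s),
        # X-II [1362, 1374)+s
        _occ("unknown", 1374 + s, 1386 + s),
        _nuc(1386 + s, 1532 + s),
        _occ("Abf1", 1532 + s, 1588 + s),
        # X-III [1588, 1600)+s
        _nuc(1600 + s, 1746 + s),
        _occ("unknown", 1746 + s, 1754 + s),
        # X-IV [1754, 1766)+s
        _occ("Tbf1", 1766 + s, 1856 + s),
        _occ("Reb1", 1856 + s, 1946 + s),
        _occ("Tbf1", 1946 + s, 2035 + s),
        # X-Y' junction at 2035+s; no accessible linker at the junction itself
        _occ("unknown", 2035 + s, 2099 + s),
        # Y'-I [2099, 2111)+s
        _occ("Abf1", 2111 + s, 2139 + s),
        _occ("unknown", 2139 + s, 2209 + s),
        # Y'-II [2209, 2221)+s: shielded; cut only under MN-Rap1 enhancement
        _occ("unknown", 2209 + s, 2221 + s, protection=0.85),
    ]
    features = [
        GenomicFeature("X_start", "element_boundary", 1281 + s, 1282 + s,
                       "paper_printed", "probe at 1281 bp from the X-element start"),
        GenomicFeature("X05R_ACS", "ACS", 1316 + s, 1333 + s,
                       "paper_printed", "X(TEL05R)-ACS located at 1325 bp from the PvuI site"),
        GenomicFeature("X_Abf1", "Abf1_site", 1538 + s, 1552 + s,
                       "paper_printed", "X-Abf1 site, 1545 bp from PvuI site"),
        GenomicFeature("XY_junction", "element_boundary", 2035 + s, 2036 + s),
        GenomicFeature("Yp_Abf1", "Abf1_site", 2103 + s, 2117 + s,
                       "paper_printed", "potential Abf1 site centered at 75 bp from the XY' junction"),
        # direct (SIR-independent) Rap1 binding over the internal X element
        GenomicFeature("Rap1_a", "Rap1_site", 1414 + s, 1427 + s, "pwm_predicted"),
        GenomicFeature("Rap1_b", "Rap1_site", 1644 + s, 1657 + s, "pwm_predicted"),
        GenomicFeature("Rap1_c", "Rap1_site", 1804 + s, 1817 + s, "pwm_predicted"),
        GenomicFeature("Rap1_d", "Rap1_site", 1924 + s, 1937 + s, "pwm_predicted"),
        GenomicFeature("Rap1_e", "Rap1_site", 2144 + s, 2157 + s, "pwm_predicted"),
        GenomicFeature("Tbf1_a", "Tbf1_site", 1770 + s, 1783 + s),
        GenomicFeature("Tbf1_b", "Tbf1_site", 1838 + s, 1851 + s),
        GenomicFeature("Reb1_a", "Reb1_site", 1870 + s, 1878 + s),
        GenomicFeature("Reb1_b", "Reb1_site", 1902 + s, 1910 + s),
        GenomicFeature("Tbf1_c", "Tbf1_site", 1958 + s, 1971 + s),
        GenomicFeature("Tbf1_d", "Tbf1_site", 1990 + s, 2003 + s),
        GenomicFeature("Reb1_c", "Reb1_site", 2010 + s, 2018 + s),
    ]
    sites = [
        GroundTruthSite("X-I", 1283.0 + s, note="ACS proximal flank"),
        GroundTruthSite("X-II", 1368.0 + s, note="ACS distal flank; X-I..X-II ~85 bp"),
        GroundTruthSite("X-III", 1594.0 + s, note="Abf1-adjacent, printed 1594 +/- 19"),
        GroundTruthSite("X-IV", 1760.0 + s),
        GroundTruthSite("Y'-I", 2105.0 + s, note="70 bp from the X-Y' junction"),
        GroundTruthSite("Y'-II", 2215.0 + s, accessibility=0.15,
                        note="MN-Rap1 specific"),
    ]
    return occupants, features, sites


def _build_x05r(genotype: str, variant: str) -> SubtelomereTemplate:
    # Internal X-Y' junction fragment of TEL05R (PvuI/PvuI), not terminal.
    length = 6502
    occupants, features, sites = _x05r_layout(shift=0)
    occupants = [
        _nuc(0, 146), _nuc(146, 292), _nuc(292, 438), _nuc(438, 584), _nuc(584, 730),
        _occ("unknown", 730, 774),
        # S-I [774, 786)
        _nuc(786, 932), _occ("unknown", 932, 939),
        # S-II [939, 951)
        _nuc(951, 1097), _occ("unknown", 1097, 1104),
        # S-III [1104, 1116)
        _occ("unknown", 1116, 1119), _nuc(1119, 1265), _occ("unknown", 1265, 1277),
        *occupants,
        # deeper Y' sites, seen mainly with the free nucleases
        _nuc(2221, 2367), _occ("unknown", 2367, 2464),
        _nuc(2476, 2622), _occ("unknown", 2622, 2694),
        _nuc(2706, 2852), _occ("unknown", 2852, 2924),
        _nuc(2936, 3082), _occ("unknown", 3082, 3154),
        # the remainder of the Y' element: a packed array, no accessible linkers
        *[_nuc(3166 + i * 146, 3166 + (i + 1) * 146) for i in range(22)],
        _occ("unknown", 6378, 6496),
    ]
    features = [
        GenomicFeature("PvuI_proximal", "restriction_site", 0, 6,
                       "paper_printed", "offsets wrt the telomere-distal PvuI site"),
        GenomicFeature("probe", "probe", 0, 100,
                       "paper_printed", "TEL05R-specific probe beside the PvuI site"),
        *features,
        GenomicFeature("PvuI_distal", "restriction_site", 6496, 6502),
    ]
    sites = [
        GroundTruthSite("S-I", 780.0),
        GroundTruthSite("S-II", 945.0),
        GroundTruthSite("S-III", 1110.0),
        *sites,
        GroundTruthSite("Y'-III", 2470.0),
        GroundTruthSite("Y'-IV", 2700.0),
        GroundTruthSite("Y'-V", 2930.0),
        GroundTruthSite("Y'-VI", 3160.0),
    ]
    return SubtelomereTemplate(
        name="X05R_AF", length=length, anchor="PvuI/left",
        features=tuple(features), occupants=tuple(occupants), probe=(0, 100),
        terminal=False, junction=2035, label_order="proximal_first",
        ground_truth_sites=tuple(sites), genotype=genotype, variant=variant,
    )


def _build_p05ra(genotype: str, variant: str) -> SubtelomereTemplate:
    # Circular plasmid carrying the TEL05R X-Y' junction; PstI-anchored probe,
    # no TG repeats and no physical end anywhere on the molecule.
    length = 3299
    shift = 1058 - 1281  # X start moves from 1281 (genomic) to 1058 (plasmid)
    occupants, features, sites = _x05r_layout(shift=shift)
    occupants = [
        *[_nuc(i * 146, (i + 1) * 146) for i in range(7)],  # plasmid backbone
        _occ("unknown", 1022, 1054),
        *occupants,
        _nuc(1998, 2144), _nuc(2144, 2290), _nuc(2290, 2436), _nuc(2436, 2582),
        _nuc(2582, 2728), _nuc(2728, 2874), _nuc(2874, 3020), _nuc(3020, 3166),
        _occ("unknown", 3166, 3293),
    ]
    features = [
        GenomicFeature("PstI", "restriction_site", 0, 6,
                       "paper_printed", "probe next to the PstI site"),
        GenomicFeature("probe", "probe", 0, 100,
                       "paper_printed", "single-strand oligo probing p05RA"),
        *features,
        GenomicFeature("NsiI", "restriction_site", 3293, 3299),
    ]
    return SubtelomereTemplate(
        name="p05RA", length=length, anchor="PstI/left",
        features=tuple(features), occupants=tuple(occupants), probe=(0, 100),
        terminal=False, junction=1812, label_order="proximal_first",
        ground_truth_sites=tuple(sites), genotype=genotype, variant=variant,
    )


def _build_x16r(genotype: str, variant: str) -> SubtelomereTemplate:
    # Internal X-Y' junction of TEL16R (BamHI/XhoI fragment).  Printed:
    # ACS-Abf1 spacing 192 bp; Y'-I at 65 +/- 4 bp from the junction; a single
    # broad ACS-centered cut (X-I) and an Abf1-adjacent cut (X-II).
    length = 3100
    occupants = [
        _nuc(0, 146), _nuc(146, 292), _nuc(292, 438), _nuc(438, 584), _nuc(584, 730),
        _occ("unknown", 730, 794),
        # S-I [794, 806)
        _nuc(806, 952), _occ("unknown", 952, 959),
        # S-II [959, 971)
        _nuc(971, 1117), _occ("unknown", 1117, 1124),
        # S-III [1124, 1136)
        _nuc(1136, 1282), _occ("unknown", 1282, 1330),
        _occ("ORC", 1330, 1371),  # abuts the upstream block: one accessible flank
        # X-I [1371, 1383)
        _nuc(1383, 1529),
        _occ("Abf1", 1529, 1557),
        _occ("unknown", 1557, 1579),
        # X-II [1579, 1591)
        _nuc(1591, 1737),
        _occ("Tbf1", 1737, 1800),
        _occ("Reb1", 1800, 1906),
        # X-Y' junction at 1906
        _occ("unknown", 1906, 1965),
        # Y'-I [1965, 1977)
        _occ("Abf1", 1977, 2005),
        *[_nuc(2005 + i * 146, 2005 + (i + 1) * 146) for i in range(7)],
        _occ("unknown", 3027, 3094),
    ]
    features = [
        GenomicFeature("BamHI", "restriction_site", 0, 6,
                       "paper_printed", "genomic digestion with BamHI and XhoI"),
        GenomicFeature("probe", "probe", 0, 100,
                       "paper_printed", "probe hybridizing at 1306 bp from the X-element start"),
        GenomicFeature("X_start", "element_boundary", 1306, 1307,
                       "paper_printed", "probe at 1306 bp from the X-element start"),
        GenomicFeature("X16R_ACS", "ACS", 1342, 1359, "reconstructed"),
        GenomicFeature("X_Abf1", "Abf1_site", 1535, 1549,
                       "paper_printed", "ACS-Abf1 spacing of 192 bp"),
        GenomicFeature("Tbf1_a", "Tbf1_site", 1745, 1758),
        GenomicFeature("Reb1_a", "Reb1_site", 1840, 1848),
        GenomicFeature("XY_junction", "element_boundary", 1906, 1907),
        GenomicFeature("Yp_Abf1", "Abf1_site", 1969, 1983, "reconstructed"),
        GenomicFeature("Rap1_a", "Rap1_site", 1620, 1633, "pwm_predicted"),
        GenomicFeature("Rap1_b", "Rap1_site", 1860, 1873, "pwm_predicted"),
        GenomicFeature("XhoI", "restriction_site", 3094, 3100),
    ]
    sites = [
        GroundTruthSite("S-I", 800.0),
        GroundTruthSite("S-II", 965.0),
        GroundTruthSite("S-III", 1130.0),
        GroundTruthSite("X-I", 1377.0, note="broad ACS-centered cut"),
        GroundTruthSite("X-II", 1585.0, note="Abf1-adjacent"),
        GroundTruthSite("Y'-I", 1971.0, note="65 bp from the X-Y' junction"),
    ]
    return SubtelomereTemplate(
        name="X16R_AF", length=length, anchor="BamHI/left",
        features=tuple(features), occupants=tuple(occupants), probe=(0, 100),
        terminal=False, junction=1906, label_order="proximal_first",
        ground_truth_sites=tuple(sites), genotype=genotype, variant=variant,
    )


def _build_trp1ars1(genotype: str, variant: str) -> SubtelomereTemplate:
    # Internal control locus: the ARS1 ACS held nucleosome free by ORC (cut
    # II to cut III, ~110 bp) flanked by strongly positioned nucleosomes.
    length = 1600
    occupants = [
        _nuc(0, 146), _occ("unknown", 146, 294),
        # I [294, 306)
        _nuc(306, 452), _occ("unknown", 452, 459),
        # II [459, 471)
        _occ("unknown", 471, 487),
        _occ("ORC", 487, 528),
        _occ("unknown", 528, 569),
        # III [569, 581)
        _nuc(581, 727), _occ("unknown", 727, 733),
        # IV [733, 745)
        _nuc(745, 891), _occ("unknown", 891, 930),
        # V [930, 942)
        _nuc(942, 1088),
        _occ("unknown", 1088, 1594),
    ]
    features = [
        GenomicFeature("XbaI", "restriction_site", 0, 6,
                       "paper_printed", "XbaI-digested genomic DNA, TRP1 probe"),
        GenomicFeature("probe", "probe", 0, 100,
                       "paper_printed", "TRP1-specific probe"),
        GenomicFeature("ARS1_ACS", "ACS", 499, 516,
                       "paper_printed", "nucleosome-free area on the ACS region"),
        GenomicFeature("XbaI_distal", "restriction_site", 1594, 1600),
    ]
    sites = [
        GroundTruthSite("I", 300.0),
        GroundTruthSite("II", 465.0),
        GroundTruthSite("III", 575.0, note="II-III ~110 bp ORC-held NFR"),
        GroundTruthSite("IV", 739.0),
        GroundTruthSite("V", 936.0),
    ]
    return SubtelomereTemplate(
        name="TRP1ARS1", length=length, anchor="XbaI/left",
        features=tuple(features), occupants=tuple(occupants), probe=(0, 100),
        terminal=False, label_order="proximal_first",
        ground_truth_sites=tuple(sites), genotype=genotype, variant=variant,
    )


_BUILDERS = {
    "YpTRF": _build_yptrf,
    "TEL03L": _build_tel03l,
    "TEL06R": _build_tel06r,
    "X05R_AF": _build_x05r,
    "X16R_AF": _build_x16r,
    "TRP1ARS1": _build_trp1ars1,
    "p05RA": _build_p05ra,
}


def build_template(name: str, genotype: str = "WT", variant: str = "") -> SubtelomereTemplate:
    """Build one of the supported templates with its ground-truth occupancy.

    Parameters
    ----------
    name:
        One of ``TEMPLATE_NAMES``.
    genotype:
        "WT", "sir" (SIR-complex deletion) or "yku" (yku80 deletion).  The
        mutants open the TEL03L site-II linker; everywhere else the planted
        occupancy is genotype-invariant, mirroring the pattern invariance of
        the junction chromatin.
    variant:
        Template-specific ground-truth alternative; for YpTRF, "orc_alone"
        leaves the ACS-adjacent short fragment bound by ORC only (the second
        model of the Y' junction), the default adds an unknown co-occupant.
    """
    if name not in _BUILDERS:
        raise ValueError(f"unknown template {name!r}; valid names: {', '.join(TEMPLATE_NAMES)}")
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; valid: {GENOTYPES}")
    return _BUILDERS[name](genotype, variant)


# ---------------------------------------------------------------------------
# Sequence synthesis
# ---------------------------------------------------------------------------

#: feature kind -> bundled matrix id used when planting motif consensus
MOTIF_FEATURE_MATRICES = {
    "Rap1_site": "MA0359.1",
    "Tbf1_site": "MA0403.1",
    "Reb1_site": "MA0363.1",
    "Abf1_site": "MA0265.1",
    "ACS": "ACS",
}


def _tg_repeat(rng: np.random.Generator, n: int) -> str:
    """Yeast telomeric repeat grammar (TG2-3(TG)1-6)n, truncated to n bases."""
    out = []
    total = 0
    while total < n:
        unit = "T" + "G" * rng.integers(2, 4) + "TG" * rng.integers(1, 7)
        out.append(unit)
        total += len(unit)
    return "".join(out)[:n]


def synthesize_sequence(template: SubtelomereTemplate, seed: int) -> str:
    """Deterministic synthetic sequence for a template.

    Motif features carry the consensus of their bundled matrix, the TG tract
    follows the telomeric repeat grammar, and everything else is uniform
    background from the seeded generator.  Raises if motif features of
    different kinds overlap (both cannot be planted).
    """
    from . import pwm  # deferred: pwm is independent of templates

    motifs = [f for f in template.features if f.kind in MOTIF_FEATURE_MATRICES]
    motifs.sort(key=lambda f: f.start)
    for a, b in zip(motifs, motifs[1:]):
        if b.start < a.end and a.kind != b.kind:
            raise ValueError(
                f"overlapping motif features of different kinds: {a.name}/{b.name}"
            )
    rng = np.random.default_rng(
        [seed & 0x7FFFFFFF, zlib.crc32(template.name.encode()) & 0x7FFFFFFF]
    )
    seq = rng.choice(list("ACGT"), size=template.length)
    matrices = pwm.bundled_matrices()
    for f in motifs:
        cons = matrices[MOTIF_FEATURE_MATRICES[f.kind]].consensus
        if len(cons) != f.end - f.start:
            raise ValueError(
                f"feature {f.name} width {f.end - f.start} != matrix length {len(cons)}"
            )
        seq[f.start:f.end] = list(cons)
    for f in template.features_of("TG_tract"):
        seq[f.start:f.end] = list(_tg_repeat(rng, f.end - f.start))
    return "".join(seq)


def with_occupants(template: SubtelomereTemplate,
                   occupants: tuple[OccupantSpec, ...]) -> SubtelomereTemplate:
    """Copy of a template with replaced ground-truth occupancy (re-validated)."""
    return replace(template, occupants=occupants)
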