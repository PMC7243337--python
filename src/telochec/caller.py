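"""Inverse analysis: band detection, indirect end-labeling and site consolidation.

Bands are local maxima of a lane profile above a prominence threshold; each
probe-anchored band of size *s* implies a preferential MNase cut at offset
*s* from the anchor restriction cut (single-cut assumption of partial
digestion).  Offsets observed across lanes, time points and constructs are
consolidated into preferential sites by single-linkage clustering and
reported as mean +/- SD with their supporting constructs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .gel import GelCalibration, LaneProfile, size_of
from .templates import SubtelomereTemplate

DEFAULT_MIN_PROMINENCE = 0.05
#: very partial H2A-MN cleavage on ice is needed to see probe-distal sites,
#: so those lanes are called with a lower prominence threshold
H2A_COLD_PROMINENCE = 0.03
DEFAULT_CLUSTER_TOLERANCE = 25.0
DIFFUSE_BASELINE_FRACTION = 0.5


@dataclass(frozen=True)
class BandCall:
    lane: object
    position: float  # profile units
    size: float  # bp
    percent_signal: float  # share of total lane intensity, [0, 100]
    prominence: float


@dataclass(frozen=True)
class SiteObservation:
    """One band converted to a cut offset, with its provenance."""

    offset: float
    construct: str
    lane: object = None
    percent_signal: float = 0.0


@dataclass(frozen=True)
class PreferentialSite:
    label: str
    mean_offset: float
    sd_offset: float
    n_observations: int
    supporting_constructs: tuple[str, ...]
    single_support: bool = False  # SD over < 2 observations
    mean_percent: float = 0.0
    template: str = ""


def detect_bands(
    profile: LaneProfile,
    calibration: GelCalibration,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    exclude_size_above: float | None = None,
    min_size: float = 60.0,
) -> list[BandCall]:
    """Call bands as prominent local maxima of the lane profile.

    ``exclude_size_above`` removes the full-length (uncut) band and, on
    terminal fragments, the TG-tract smear; percent_signal integrates the
    profile over +/- 2 band sigma around each peak.
    """
    if not 0.0 < min_prominence < 1.0:
        raise ValueError("min_prominence must lie in (0, 1)")
    y = profile.intensity
    top = float(y.max(initial=0.0))
    if top <= 0:
        return []
    idx, props = find_peaks(y, prominence=min_prominence * top)
    if idx.size == 0:
        return []
    step = profile.step
    total = float(y.sum() * step)
    half = max(1, int(round(2.0 * profile.band_sigma / step)))
    calls = []
    for i, prom in zip(idx, props["prominences"]):
        lo, hi = max(0, i - half), min(y.size, i + half + 1)
        w = y[lo:hi]
        # centroid refinement for sub-bin peak position
        center = float((profile.positions[lo:hi] * w).sum() / w.sum())
        size = size_of(center, calibration)
        if size < min_size:
            continue
        if exclude_size_above is not None and size > exclude_size_above:
            continue
        calls.append(
            BandCall(
                lane=profile.lane,
                position=center,
                size=float(size),
                percent_signal=100.0 * float(w.sum() * step) / total,
                prominence=float(prom / top),
            )
        )
    calls.sort(key=lambda b: b.size)
    return calls


def sizes_to_cut_offsets(bands, template: SubtelomereTemplate) -> np.ndarray:
    """Map probe-anchored band sizes to cut offsets from the anchor.

    With the probe abutting the anchor restriction cut, a fragment of size s
    implies a cut at offset s (single-cut assumption).  Fragments larger
    than the template (max TG tract included) are rejected.
    """
    sizes = np.array([b.size for b in bands], dtype=float)
    limit = template.length
    if template.terminal:
        from .templates import TG_TRUNCATION

        limit = template.core_length + TG_TRUNCATION[1]
    if (sizes > limit).any():
        raise ValueError("fragment larger than the template")
    return sizes


def consolidate(
    observations,
    tolerance: float = DEFAULT_CLUSTER_TOLERANCE,
    label_order: str = "proximal_first",
    all_constructs=None,
    template: str = "",
) -> list[PreferentialSite]:
    """Cluster cut-offset observations into preferential sites.

    Single-linkage clustering with linkage distance <= ``tolerance`` (in 1-D
    this is: split sorted offsets where adjacent gaps exceed the tolerance).
    Sites are labeled with Roman numerals ordered proximal-to-distal along
    the fragment; terminal-fragment convention (``label_order =
    "distal_first"``) starts numbering at the telomere-proximal site, as on
    the gels.  A site is "common" when supported by every free construct of
    the experiment.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    obs = [
        o if isinstance(o, SiteObservation) else SiteObservation(float(o), "?")
        for o in observations
    ]
    if not obs:
        return []
    obs.sort(key=lambda o: o.offset)
    clusters: list[list[SiteObservation]] = [[obs[0]]]
    for o in obs[1:]:
        if o.offset - clusters[-1][-1].offset <= tolerance:
            clusters[-1].append(o)
        else:
            clusters.append([o])
    if label_order == "distal_first":
        ordered = list(reversed(clusters))
    else:
        ordered = clusters
    sites = []
    for k, cl in enumerate(ordered):
        offs = np.array([o.offset for o in cl])
        sites.append(
            PreferentialSite(
                label=_roman(k + 1),
                mean_offset=float(offs.mean()),
                sd_offset=float(offs.std(ddof=1)) if offs.size > 1 else 0.0,
                n_observations=int(offs.size),
                supporting_constructs=tuple(sorted({o.construct for o in cl})),
                single_support=offs.size < 2,
                mean_percent=float(np.mean([o.percent_signal for o in cl])),
                template=template,
            )
        )
    sites.sort(key=lambda s: s.mean_offset)
    return sites


def is_common(site: PreferentialSite, free_constructs) -> bool:
    """Common sites are supported by all free constructs (solid arrowheads)."""
    return all(c in site.supporting_constructs for c in free_constructs)


def diffuse_regions(profile: LaneProfile, bands, calibration: GelCalibration):
    """Flag inter-band regions with high baseline cutting.

    A region between consecutive bands is "diffuse" when the minimum profile
    intensity between the two peaks exceeds half the smaller flanking peak
    height -- the operational reading of a non-negligible diffuse signal
    between preferential cut sites.
    """
    out = []
    ordered = sorted(bands, key=lambda b: b.position)
    pos = profile.positions
    for left, right in zip(ordered, ordered[1:]):
        i0 = int(np.searchsorted(pos, left.position))
        i1 = int(np.searchsorted(pos, right.position))
        if i1 <= i0 + 1:
            continue
        baseline = float(profile.intensity[i0:i1 + 1].min())
        flank = min(
            float(profile.intensity[min(i0, pos.size - 1)]),
            float(profile.intensity[min(i1, pos.size - 1)]),
        )
        ratio = baseline / flank if flank > 0 else 0.0
        out.append(
            {
                "left_size": left.size,
                "right_size": right.size,
                "baseline_ratio": ratio,
                "diffuse": ratio > DIFFUSE_BASELINE_FRACTION,
            }
        )
    return out


def _roman(n: int) -> str:
    vals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
            (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
            (5, "V"), (4, "IV"), (1, "I")]
    out = []
    for v, sym in vals:
        while n >= v:
            out.append(sym)
            n -= v
    return "".join(out)
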