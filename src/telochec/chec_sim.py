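"""Forward model of in vivo ChEC partial digestion.

A lane (one construct x digestion time x temperature) is simulated molecule
by molecule: cut events form an inhomogeneous Poisson process with per-bp
mean ``k * a(x) * c(x) * temperature_factor * time`` where

* ``a(x)`` is the accessibility profile: 1 on naked DNA, ``1 - protection``
  inside each ground-truth occupant footprint;
* ``c(x)`` is the relative local concentration of the MNase fusion: 1 for
  free nucleases (GBD-MN, NLS-MN), elevated by a box kernel around the
  anchors of tethered ones (MN-Rap1 at Rap1 sites and the TG tract, H2A-MN
  at nucleosomes, Yku70-MN at the physical chromosome end).

Detection mimics indirect end-labeling with a probe abutting the anchor
restriction cut: per molecule only the probe-overlapping fragment (anchor to
first cut, or the full restriction fragment when uncut) is retained.
Terminal fragments draw a per-molecule TG-tract length from the
heterogeneous tract model, producing the characteristic full-length smear.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .templates import SubtelomereTemplate, TG_TRUNCATION

TEMPERATURE_FACTORS = {"30C": 1.0, "4C": 0.05}

#: default digestion schedule used by the experiment driver: three 30 C
#: points covering partial to near-complete digestion plus the on-ice
#: points needed to see probe-distal sites under very partial cleavage
DEFAULT_SCHEDULE = ((1.0, "30C"), (2.0, "30C"), (5.0, "30C"),
                    (5.0, "4C"), (15.0, "4C"))


@dataclass(frozen=True)
class MNConstruct:
    """An MNase fusion construct and its tethering behaviour."""

    name: str
    tether: str  # "free" | "site" | "nucleosome" | "chromosome_end"
    enhancement: float = 0.0  # lambda, local rate multiplier amplitude
    reach: float = 0.0  # d, half-width of the box kernel, bp
    anchor_kinds: tuple[str, ...] = ()  # feature kinds anchoring the kernel

    def __post_init__(self):
        if self.tether == "free":
            if self.enhancement != 0:
                raise ValueError("free constructs must have zero enhancement")
        else:
            if self.enhancement <= 0 or self.reach <= 0:
                raise ValueError("tethered constructs need enhancement > 0 and reach > 0")


CONSTRUCTS: dict[str, MNConstruct] = {
    "GBD-MN": MNConstruct("GBD-MN", "free"),
    "NLS-MN": MNConstruct("NLS-MN", "free"),
    "MN-Rap1": MNConstruct("MN-Rap1", "site", enhancement=10.0, reach=200.0,
                           anchor_kinds=("Rap1_site", "TG_tract")),
    "H2A-MN": MNConstruct("H2A-MN", "nucleosome", enhancement=1.0, reach=80.0),
    "Yku70-MN": MNConstruct("Yku70-MN", "chromosome_end", enhancement=10.0, reach=150.0),
}

FREE_CONSTRUCTS = ("GBD-MN", "NLS-MN")


def get_construct(name: str) -> MNConstruct:
    try:
        return CONSTRUCTS[name]
    except KeyError:
        raise ValueError(f"unknown construct {name!r}; valid: {sorted(CONSTRUCTS)}") from None


@dataclass(frozen=True)
class DigestionParams:
    n_molecules: int = 2000
    time_points: tuple[float, ...] = (0.0, 1.0, 2.0, 5.0, 15.0)
    base_rate: float = 0.04  # k, cuts per accessible bp per minute at 30 C
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if any(t < 0 for t in self.time_points):
            raise ValueError("time points must be >= 0")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be > 0")


@dataclass(frozen=True)
class LaneId:
    template: str
    genotype: str
    construct: str
    time: float
    temperature: str

    def __str__(self):
        return f"{self.template}:{self.genotype}:{self.construct}:{self.time:g}min:{self.temperature}"


@dataclass
class FragmentPopulation:
    """Probe-detected fragment lengths for one lane."""

    lane: LaneId
    fragments: np.ndarray  # bp, one per molecule (probe-anchored fragment)
    n_molecules: int
    full_lengths: np.ndarray | None = None  # per-molecule restriction fragment length


def derive_seed(master_seed: int, *parts) -> int:
    """Stable per-lane seed below 2**31 derived from the master seed."""
    h = hashlib.sha256("|".join([str(master_seed), *map(str, parts)]).encode())
    return int.from_bytes(h.digest()[:4], "big") & 0x7FFFFFFF


def accessibility_profile(template: SubtelomereTemplate) -> np.ndarray:
    """Per-bp accessibility a(x) in [0, 1] over the nominal template length."""
    a = np.ones(template.length)
    for occ in template.occupants:
        a[occ.start:occ.end] = 1.0 - occ.effective_protection
    return a


def concentration_profile(template: SubtelomereTemplate, construct: MNConstruct) -> np.ndarray:
    """Relative local nuclease concentration c(x) >= 1 (box kernels at anchors)."""
    c = np.ones(template.length)
    if construct.tether == "free" or construct.enhancement == 0:
        return c
    centers: list[float] = []
    if construct.tether == "nucleosome":
        centers = [0.5 * (o.start + o.end) for o in template.occupants
                   if o.protein == "nucleosome"]
    elif construct.tether == "chromosome_end":
        if template.terminal:
            centers = [float(template.length)]
    else:  # site-tethered: anchor on the declared feature kinds
        for f in template.features:
            if f.kind in construct.anchor_kinds:
                centers.append(f.center)
    x = np.arange(template.length) + 0.5
    for m in centers:
        c[np.abs(x - m) <= construct.reach] += construct.enhancement
    return c


def _draw_tract_lengths(template: SubtelomereTemplate, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    mean, sd = template.tg_length_model
    lo, hi = TG_TRUNCATION
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_lane(
    template: SubtelomereTemplate,
    construct: MNConstruct | str,
    params: DigestionParams,
    time: float,
    temperature: str = "30C",
    keep_all: bool = False,
) -> FragmentPopulation:
    """Simulate one gel lane.

    ``time`` must belong to ``params.time_points`` (lanes follow the declared
    time course).  With ``keep_all`` the per-molecule pre-filter fragment
    lists are retained (their lengths sum to each molecule's full length).
    """
    if isinstance(construct, str):
        construct = get_construct(construct)
    if not any(np.isclose(time, t) for t in params.time_points):
        raise ValueError(f"time {time} not in declared time points {params.time_points}")
    if temperature not in TEMPERATURE_FACTORS:
        raise ValueError(f"unknown temperature regime {temperature!r}")
    lane = LaneId(template.name, template.genotype, construct.name, float(time), temperature)
    rng = np.random.default_rng(derive_seed(params.seed, lane))
    n = params.n_molecules
    tf = TEMPERATURE_FACTORS[temperature]
    core = template.core_length

    a = accessibility_profile(template)
    c = concentration_profile(template, construct)
    rate = params.base_rate * tf * time * a[:core] * c[:core]
    lam_core = float(rate.sum())

    if template.terminal:
        tract = _draw_tract_lengths(template, n, rng)
        full = core + tract
        a_tract = a[core:].mean() if a.size > core else 0.01
        c_tract = c[core:].mean() if c.size > core else 1.0
        lam_tract = params.base_rate * tf * time * a_tract * c_tract * tract
    else:
        full = np.full(n, float(template.length))
        lam_tract = np.zeros(n)

    first_cut = full.copy()
    all_cuts: list[np.ndarray] | None = [np.empty(0)] * n if keep_all else None

    if lam_core > 0:
        counts = rng.poisson(lam_core, size=n)
        total = int(counts.sum())
        if total:
            pos = rng.choice(core, size=total, p=rate / lam_core) + rng.random(total)
            splits = np.split(pos, np.cumsum(counts)[:-1])
            for i, p in enumerate(splits):
                if p.size:
                    first_cut[i] = min(first_cut[i], p.min())
                    if keep_all:
                        all_cuts[i] = p
    if template.terminal and time > 0:
        tcounts = rng.poisson(lam_tract)
        for i in np.nonzero(tcounts)[0]:
            tp = core + rng.random(tcounts[i]) * (full[i] - core)
            first_cut[i] = min(first_cut[i], tp.min())
            if keep_all:
                all_cuts[i] = np.concatenate([all_cuts[i], tp])

    pop = FragmentPopulation(lane, first_cut, n, full_lengths=full)
    if keep_all:
        pop.all_fragments = [
            np.diff(np.concatenate([[0.0], np.sort(cuts), [full[i]]]))
            for i, cuts in enumerate(all_cuts)
        ]
    return pop


def simulate_experiment(
    template: SubtelomereTemplate,
    constructs,
    params: DigestionParams,
    schedule=DEFAULT_SCHEDULE,
) -> list[FragmentPopulation]:
    """One lane per construct x (time, temperature) in the schedule."""
    lanes = []
    for con in constructs:
        for time, temp in schedule:
            lanes.append(simulate_lane(template, con, params, time, temp))
    return lanes


def expected_cuts(
    template: SubtelomereTemplate,
    construct: MNConstruct | str,
    params: DigestionParams,
    time: float,
    temperature: str = "30C",
) -> float:
    """Closed-form mean number of cuts per molecule (nominal tract length)."""
    if isinstance(construct, str):
        construct = get_construct(construct)
    tf = TEMPERATURE_FACTORS[temperature]
    a = accessibility_profile(template)
    c = concentration_profile(template, construct)
    return params.base_rate * tf * time * float((a * c).sum())
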