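"""Virtual Southern blot: lane rendering and log-linear fragment sizing.

Fragments migrate according to ``m(s) = a - b * log10(s)`` (position in
profile units, size in bp, b > 0 so large fragments migrate less).  Probe
detection is count-proportional: each detected fragment carries exactly one
hybridization event, so a band's area equals its fragment count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d


@dataclass(frozen=True)
class GelCalibration:
    intercept: float  # a
    slope: float  # b > 0
    residual_rms: float = 0.0
    span: tuple[float, float] | None = None  # (min, max) ladder size, bp

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("slope must be > 0 (larger fragments migrate less)")

    def migration(self, size) -> np.ndarray:
        size = np.asarray(size, dtype=float)
        if (size <= 0).any():
            raise ValueError("fragment sizes must be > 0")
        return self.intercept - self.slope * np.log10(size)


#: default migration law.  The default band sigma makes species ~6.5 % apart
#: in size (e.g. 85 bp at 1.3 kb, the finest spacing the modeled Southern
#: blots resolve) sit ~4 sigma apart; bands 20 % apart are widely resolvable.
DEFAULT_CALIBRATION = GelCalibration(intercept=735.0, slope=180.0)
DEFAULT_BAND_SIGMA = DEFAULT_CALIBRATION.slope * np.log10(1.065) / 4.0  # ~1.23 units
DEFAULT_AXIS_STEP = 0.25

#: stand-in size ladder, log-spaced over 0.1-10 kb
LADDER_SIZES = (100, 200, 300, 400, 500, 650, 850, 1000, 1650,
                2000, 3000, 4000, 5000, 6000, 8000, 10000)


@dataclass
class LaneProfile:
    """1-D densitometry profile of one lane plus its ladder."""

    positions: np.ndarray  # migration axis, profile units, increasing
    intensity: np.ndarray  # >= 0, same shape
    lane: object = None
    ladder: tuple = ()  # ((size_bp, position), ...), decreasing in size
    band_sigma: float = DEFAULT_BAND_SIGMA

    @property
    def step(self) -> float:
        return float(self.positions[1] - self.positions[0])

    @property
    def total_area(self) -> float:
        return float(self.intensity.sum() * self.step)


def default_axis(step: float = DEFAULT_AXIS_STEP) -> np.ndarray:
    """Migration axis covering ~30 bp to ~12 kb under the default law."""
    return np.arange(0.0, 560.0 + step, step)


def make_ladder(
    calibration: GelCalibration = DEFAULT_CALIBRATION,
    sizes=LADDER_SIZES,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Ladder observations (size, position), optionally with position noise."""
    pos = calibration.migration(np.asarray(sizes, float))
    if noise_sd > 0:
        rng = rng or np.random.default_rng()
        pos = pos + rng.normal(0.0, noise_sd, size=pos.shape)
    return tuple(zip([float(s) for s in sizes], [float(p) for p in pos]))


def render_lane(
    population,
    calibration: GelCalibration = DEFAULT_CALIBRATION,
    band_sigma: float = DEFAULT_BAND_SIGMA,
    axis: np.ndarray | None = None,
    ladder=None,
) -> LaneProfile:
    """Render a fragment population into a lane profile.

    Each fragment contributes a unit-area Gaussian at its migration
    position; total profile area therefore equals the number of detected
    fragments.  Deterministic given the population.
    """
    if band_sigma <= 0:
        raise ValueError("band_sigma must be > 0")
    fragments = np.asarray(getattr(population, "fragments", population), dtype=float)
    if (fragments <= 0).any():
        raise ValueError("fragment sizes must be > 0")
    if axis is None:
        axis = default_axis()
    step = float(axis[1] - axis[0])
    intensity = np.zeros(axis.size)
    if fragments.size:
        pos = calibration.migration(fragments)
        edges = np.concatenate([axis - step / 2, [axis[-1] + step / 2]])
        counts, _ = np.histogram(np.clip(pos, edges[0], edges[-1] - 1e-9), bins=edges)
        intensity = gaussian_filter1d(counts.astype(float) / step, band_sigma / step,
                                      mode="constant")
    if ladder is None:
        ladder = make_ladder(calibration)
    return LaneProfile(
        positions=axis,
        intensity=intensity,
        lane=getattr(population, "lane", None),
        ladder=tuple(ladder),
        band_sigma=band_sigma,
    )


def calibrate(ladder) -> GelCalibration:
    """Least-squares fit of migration position on log10(size)."""
    ladder = list(ladder)
    sizes = np.array([s for s, _ in ladder], dtype=float)
    pos = np.array([p for _, p in ladder], dtype=float)
    if sizes.size < 2 or np.unique(sizes).size < 2:
        raise ValueError("calibration needs at least 2 distinct ladder sizes")
    logs = np.log10(sizes)
    slope, intercept = np.polyfit(logs, pos, 1)
    fitted = intercept + slope * logs
    rms = float(np.sqrt(np.mean((pos - fitted) ** 2)))
    return GelCalibration(
        intercept=float(intercept), slope=float(-slope), residual_rms=rms,
        span=(float(sizes.min()), float(sizes.max())),
    )


def size_of(position, calibration: GelCalibration):
    """Invert the migration law: s = 10 ** ((a - position) / b).

    Extrapolation beyond the ladder span is allowed; use
    ``in_ladder_span`` to flag it.
    """
    position = np.asarray(position, dtype=float)
    s = 10.0 ** ((calibration.intercept - position) / calibration.slope)
    return float(s) if s.ndim == 0 else s


def in_ladder_span(size, calibration: GelCalibration) -> bool:
    if calibration.span is None:
        return True
    lo, hi = calibration.span
    return bool(lo <= size <= hi)
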