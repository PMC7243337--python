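"""Position-weight-matrix scanning with exact tail p-values.

Log-odds scoring from count matrices and exact score p-values by dynamic
programming over a rounded score grid, as used for annotating GRF (Rap1,
Tbf1, Reb1, Abf1) and ACS/ORC binding sites on subtelomeric sequences.
Default per-matrix p-value cutoffs follow the annotation protocol:
0.001 for Rap1/Reb1/Abf1, 0.005 for Tbf1 and 1e-6 for the ACS matrix.

The bundled matrices (``data/synthetic_matrices.jaspar``) are synthetic
stand-ins constructed from published consensus sequences and carry the
corresponding JASPAR identifiers as labels only; absolute genome-scale hit
counts obtained with them are not comparable to scans with the curated
matrices.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import motifs as bio_motifs

ALPHABET = "ACGT"
_INDEX = {b: i for i, b in enumerate(ALPHABET)}

UNIFORM_BACKGROUND = np.full(4, 0.25)
DEFAULT_PSEUDOCOUNT = 0.8
DEFAULT_GRANULARITY = 0.01  # bits

#: matrix id -> default p-value cutoff for site calling
DEFAULT_P_THRESHOLDS = {
    "MA0359.1": 1e-3,  # Rap1
    "MA0363.1": 1e-3,  # Reb1
    "MA0265.1": 1e-3,  # Abf1
    "MA0403.1": 5e-3,  # Tbf1
    "ACS": 1e-6,
}


@dataclass(frozen=True)
class CountMatrix:
    """A 4 x L nucleotide count matrix (rows in ACGT order)."""

    id: str
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != 4 or c.shape[1] < 1:
            raise ValueError("counts must be a 4 x L array")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        """Argmax base per column; ties resolved in ACGT order."""
        return "".join(ALPHABET[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class ScoredSite:
    position: int  # 0-based window start on the forward strand
    strand: str  # "+" or "-"
    score: float  # log2 odds
    p_value: float
    matrix_id: str = ""


def log_odds(
    counts: CountMatrix | np.ndarray,
    background: np.ndarray = UNIFORM_BACKGROUND,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> np.ndarray:
    """Log2-odds matrix from counts with background-split pseudocount.

    entry(b, j) = log2((n_bj + pc * bg_b) / (N_j + pc)) - log2(bg_b).
    """
    c = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts, float)
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any() or abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must be 4 positive frequencies summing to 1")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    totals = c.sum(axis=0)
    if pseudocount == 0 and (totals == 0).any():
        raise ValueError("zero column totals require a positive pseudocount")
    freq = (c + pseudocount * bg[:, None]) / (totals + pseudocount)[None, :]
    with np.errstate(divide="ignore"):
        # individual zero counts with zero pseudocount yield -inf entries
        return np.log2(freq) - np.log2(bg)[:, None]


def score_distribution(
    matrix: np.ndarray,
    background: np.ndarray = UNIFORM_BACKGROUND,
    granularity: float = DEFAULT_GRANULARITY,
) -> tuple[np.ndarray, int]:
    """Exact distribution of the window score on the rounded grid.

    Returns (probabilities, min_index): probabilities[k] is the chance that a
    background-drawn window has quantized total score min_index + k (in
    granularity units).
    """
    if granularity <= 0:
        raise ValueError("granularity must be > 0")
    bg = np.asarray(background, dtype=float)
    m = np.asarray(matrix, float)
    finite = np.isfinite(m)
    if not finite.any(axis=0).all():
        # some column is entirely unattainable: no finite-scoring window
        return np.zeros(1), 0
    q = np.zeros_like(m, dtype=np.int64)
    q[finite] = np.rint(m[finite] / granularity).astype(np.int64)
    # -inf entries (impossible bases) drop their probability mass: windows
    # containing them score below any finite query, so they never enter a tail
    lo = int(np.where(finite, q, np.iinfo(np.int64).max).min(axis=0).sum())
    hi = int(np.where(finite, q, np.iinfo(np.int64).min).max(axis=0).sum())
    dist = np.zeros(hi - lo + 1)
    dist[0] = 1.0
    for j in range(q.shape[1]):
        col = q[:, j]
        ok = finite[:, j]
        cmin = int(col[ok].min())
        new = np.zeros_like(dist)
        for b in range(4):
            if ok[b] and bg[b] > 0:
                shift = int(col[b]) - cmin
                new[shift:] += bg[b] * dist[: dist.size - shift if shift else None]
        dist = new
    return dist, lo


def pvalue_exact(
    matrix: np.ndarray,
    score: float,
    background: np.ndarray = UNIFORM_BACKGROUND,
    granularity: float = DEFAULT_GRANULARITY,
) -> float:
    """P(window score >= score) for a background-drawn window.

    Computed by convolving per-column score distributions on a grid of step
    ``granularity``; the quantization error is bounded by L * granularity / 2
    score units and is absorbed into the tail threshold.
    """
    if not np.isfinite(score):
        return 1.0 if score < 0 else 0.0
    dist, lo = score_distribution(matrix, background, granularity)
    L = np.asarray(matrix).shape[1]
    # tolerance so that a score attainable exactly is never rounded out
    idx = int(np.ceil((score - 1e-12) / granularity - 0.5 * L)) - lo
    if idx <= 0:
        return 1.0
    if idx >= dist.size:
        return 0.0
    return float(dist[idx:].sum())


def _encode(sequence: str) -> np.ndarray:
    idx = np.fromiter((_INDEX.get(b, 4) for b in sequence.upper()), dtype=np.int64,
                      count=len(sequence))
    return idx


def _window_scores(idx: np.ndarray, matrix: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Scores of all windows; ambiguity codes score the background average."""
    L = matrix.shape[1]
    if idx.size < L:
        return np.empty(0)
    expected = (background[:, None] * matrix).sum(axis=0)
    m5 = np.vstack([matrix, expected])  # row 4 = ambiguity
    win = np.lib.stride_tricks.sliding_window_view(idx, L)
    return m5[win, np.arange(L)].sum(axis=1)


def reverse_complement_matrix(matrix: np.ndarray) -> np.ndarray:
    """Log-odds matrix scanning the reverse strand of a forward window."""
    return matrix[::-1, ::-1]


def call_sites(
    sequence: str,
    matrix: CountMatrix,
    p_threshold: float | None = None,
    background: np.ndarray = UNIFORM_BACKGROUND,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    granularity: float = DEFAULT_GRANULARITY,
) -> list[ScoredSite]:
    """Scan both strands and return every window with p_value < p_threshold.

    All overlapping calls are reported, sorted by position.  A sequence
    shorter than the matrix yields an empty list.
    """
    if p_threshold is None:
        p_threshold = DEFAULT_P_THRESHOLDS.get(matrix.id, 1e-3)
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must lie in (0, 1)")
    lom = log_odds(matrix, background, pseudocount)
    dist, lo = score_distribution(lom, background, granularity)
    tail = dist[::-1].cumsum()[::-1]
    L = lom.shape[1]
    idx = _encode(sequence)

    def lookup_p(scores: np.ndarray) -> np.ndarray:
        k = np.ceil((scores - 1e-12) / granularity - 0.5 * L).astype(np.int64) - lo
        k = np.clip(k, 0, tail.size)
        p = np.ones_like(scores)
        inside = k < tail.size
        p[inside & (k > 0)] = tail[k[inside & (k > 0)]]
        p[k >= tail.size] = 0.0
        return p

    out: list[ScoredSite] = []
    for strand, m in (("+", lom), ("-", reverse_complement_matrix(lom))):
        scores = _window_scores(idx, m, background)
        if scores.size == 0:
            continue
        pvals = lookup_p(scores)
        for pos in np.nonzero(pvals < p_threshold)[0]:
            out.append(
                ScoredSite(int(pos), strand, float(scores[pos]), float(pvals[pos]),
                           matrix.id)
            )
    out.sort(key=lambda s: (s.position, s.strand))
    return out


@lru_cache(maxsize=1)
def bundled_matrices() -> dict[str, CountMatrix]:
    """The synthetic stand-in count matrices shipped with the package."""
    ref = importlib.resources.files("telochec").joinpath("data/synthetic_matrices.jaspar")
    with ref.open() as handle:
        parsed = bio_motifs.parse(handle, "jaspar")
        out = {}
        for m in parsed:
            counts = np.array([list(m.counts[b]) for b in ALPHABET], dtype=float)
            out[m.matrix_id] = CountMatrix(m.matrix_id, counts)
    return out


def read_jaspar(path) -> dict[str, CountMatrix]:
    """Read count matrices from a JASPAR-format file."""
    with open(path) as handle:
        parsed = bio_motifs.parse(handle, "jaspar")
        return {
            m.matrix_id: CountMatrix(
                m.matrix_id, np.array([list(m.counts[b]) for b in ALPHABET], float)
            )
            for m in parsed
        }
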