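"""Observer-independent detection of cytoarchitectonic borders.

A sliding window groups adjacent profile feature vectors into two abutting
blocks of equal size b; the Mahalanobis distance (MD) between the block means,
weighted by the pooled within-block covariance, is plotted as a distance
function over all block positions.  Local MD maxima that survive a Hotelling
T^2 test with Bonferroni correction, remain stable across block sizes 10-24,
and recur in at least three consecutive sections are accepted as borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

DEFAULT_BLOCK_RANGE = tuple(range(10, 25))


@dataclass(frozen=True)
class DistanceFunction:
    """MD per admissible block position for one block size."""

    positions: np.ndarray  # profile index of the first right-block profile
    md: np.ndarray
    block_size: int

    def __post_init__(self):
        if np.any(np.asarray(self.md) < -1e-12):
            raise ValueError("Mahalanobis distances must be nonnegative")


@dataclass(frozen=True)
class BorderCandidate:
    """A block-size-stable significant MD maximum."""

    position: int
    block_sizes_supporting: tuple[int, ...]
    min_corrected_p: float
    confirmed_sections: int = 0

    def __post_init__(self):
        if not 0.0 <= self.min_corrected_p <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if len(self.block_sizes_supporting) == 0:
            raise ValueError("candidate must be supported by at least one block size")


def _pooled_cov(left: np.ndarray, right: np.ndarray, shrinkage) -> np.ndarray:
    """Bias-corrected pooled within-block covariance, optionally shrunk
    toward its diagonal when small blocks make it ill-conditioned."""
    n1, n2 = left.shape[0], right.shape[0]
    s1 = np.cov(left, rowvar=False, ddof=1)
    s2 = np.cov(right, rowvar=False, ddof=1)
    s = ((n1 - 1) * np.atleast_2d(s1) + (n2 - 1) * np.atleast_2d(s2)) / (n1 + n2 - 2)
    p = s.shape[0]
    if shrinkage is None or shrinkage == 0:
        return s
    target = np.diag(np.diag(s))
    if shrinkage == "auto":
        # shrink only when small blocks leave the estimate rank-deficient or
        # ill-conditioned; otherwise keep the exact pooled covariance so MD
        # stays affine-invariant
        df = n1 + n2 - 2
        cond = np.linalg.cond(s) if np.all(np.isfinite(s)) else np.inf
        if df > p and cond < 1e8:
            return s
        shrinkage = max(0.1, min(1.0, p / max(df, 1)))
    return (1 - shrinkage) * s + shrinkage * target


def mahalanobis_distance(left: np.ndarray, right: np.ndarray,
                         shrinkage="auto") -> float:
    """MD between the mean feature vectors of two profile blocks.

    MD^2 = (m_L - m_R)' S_pooled^-1 (m_L - m_R).
    """
    left = np.atleast_2d(np.asarray(left, float))
    right = np.atleast_2d(np.asarray(right, float))
    if left.shape[0] < 2 or right.shape[0] < 2:
        raise ValueError("block_size must be >= 2")
    if left.shape[1] != right.shape[1]:
        raise ValueError("blocks must share the feature dimension")
    s = _pooled_cov(left, right, shrinkage)
    d = left.mean(axis=0) - right.mean(axis=0)
    try:
        sol = np.linalg.solve(s, d)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"pooled covariance not invertible: {e}") from e
    md2 = float(d @ sol)
    return float(np.sqrt(max(md2, 0.0)))


def hotelling_test(left: np.ndarray, right: np.ndarray) -> float:
    """Two-sample Hotelling T^2 p-value via the exact F transformation.

    Uses the plain pooled covariance (the exact null distribution requires
    it); with one feature this reduces to the two-sided pooled-variance
    t-test (T^2 = t^2).
    """
    left = np.atleast_2d(np.asarray(left, float))
    right = np.atleast_2d(np.asarray(right, float))
    n1, n2 = left.shape[0], right.shape[0]
    p = left.shape[1]
    if n1 + n2 - 2 <= p:
        raise ValueError(
            f"Hotelling test needs n1+n2-2 > p (got n1+n2-2={n1 + n2 - 2}, p={p})")
    md = mahalanobis_distance(left, right, shrinkage=None)
    if not np.isfinite(md):
        raise ValueError("degenerate pooled covariance in Hotelling test")
    t2 = (n1 * n2) / (n1 + n2) * md ** 2
    n = n1 + n2
    f = t2 * (n - p - 1) / (p * (n - 2))
    return float(stats.f.sf(f, p, n - p - 1))


def distance_function(features: np.ndarray, block_size: int,
                      shrinkage="auto") -> DistanceFunction:
    """Sliding-window MD between immediately adjacent blocks, one-profile steps.

    Position k holds the MD between profiles [k-b, k) and [k, k+b).
    """
    feats = np.asarray(features, float)
    n = feats.shape[0]
    b = int(block_size)
    if b < 2:
        raise ValueError("block_size must be >= 2")
    if n < 2 * b:
        raise ValueError(f"need at least 2*block_size={2 * b} profiles, got {n}")
    positions = np.arange(b, n - b + 1)
    md = np.empty(positions.size)
    for i, k in enumerate(positions):
        md[i] = mahalanobis_distance(feats[k - b:k], feats[k:k + b], shrinkage=shrinkage)
    return DistanceFunction(positions=positions, md=md, block_size=b)


def _local_maxima(md: np.ndarray) -> list[int]:
    """Indices of strict local maxima; plateaus take the centre index
    (ties broken to the lower index)."""
    out = []
    n = md.size
    i = 1
    while i < n - 1:
        if md[i] > md[i - 1]:
            j = i
            while j + 1 < n and md[j + 1] == md[i]:
                j += 1
            if j + 1 < n and md[j + 1] < md[i]:
                out.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return out


def detect_borders(features: np.ndarray,
                   block_range=DEFAULT_BLOCK_RANGE,
                   alpha: float = 0.05,
                   stability_window: int = 2,
                   stability_fraction: float = 0.5,
                   shrinkage="auto") -> list[BorderCandidate]:
    """Detect statistically validated borders along a ribbon of feature vectors.

    For each block size, local MD maxima passing Bonferroni-corrected
    Hotelling tests (family = number of block positions at that size) are
    collected; maxima within ±stability_window profiles are merged across
    block sizes, and a candidate survives only when supported by at least
    ``stability_fraction`` of the block sizes.
    """
    feats = np.asarray(features, float)
    block_range = tuple(int(b) for b in block_range)
    n = feats.shape[0]
    if n < 2 * max(block_range):
        raise ValueError("too few profiles for the largest block size")
    hits: list[tuple[int, int, float]] = []  # (position, block size, corrected p)
    for b in block_range:
        df = distance_function(feats, b, shrinkage=shrinkage)
        family = df.positions.size
        for im in _local_maxima(df.md):
            k = int(df.positions[im])
            p_raw = hotelling_test(feats[k - b:k], feats[k:k + b])
            p_corr = min(1.0, p_raw * family)
            if p_corr <= alpha:
                hits.append((k, b, p_corr))
    if not hits:
        return []
    hits.sort()
    # greedy clustering of positions within the stability window
    clusters: list[list[tuple[int, int, float]]] = []
    for h in hits:
        if clusters and h[0] - clusters[-1][0][0] <= stability_window:
            clusters[-1].append(h)
        else:
            clusters.append([h])
    min_support = stability_fraction * len(block_range)
    out = []
    for cl in clusters:
        bs = tuple(sorted({b for _, b, _ in cl}))
        if len(bs) >= min_support:
            pos = int(round(float(np.median([k for k, _, _ in cl]))))
            out.append(BorderCandidate(
                position=pos,
                block_sizes_supporting=bs,
                min_corrected_p=min(p for _, _, p in cl)))
    return sorted(out, key=lambda c: c.position)


def confirm_across_sections(candidate_lists: list[list[BorderCandidate]],
                            tolerance: int = 3) -> list[BorderCandidate]:
    """Keep borders that recur, within ±tolerance profiles, in at least three
    consecutive sections; the confirmed position is the median of the matched
    positions.  Excludes biologically meaningless maxima caused by local
    artefacts in single sections."""
    if len(candidate_lists) < 3:
        raise ValueError("need candidate lists from at least 3 consecutive sections")
    confirmed: list[BorderCandidate] = []
    for start in range(len(candidate_lists) - 2):
        for cand in candidate_lists[start]:
            chain = [cand.position]
            p_min = cand.min_corrected_p
            ref = cand.position
            for nxt in candidate_lists[start + 1:]:
                matches = [c for c in nxt if abs(c.position - ref) <= tolerance]
                if not matches:
                    break
                best = min(matches, key=lambda c: abs(c.position - ref))
                chain.append(best.position)
                p_min = min(p_min, best.min_corrected_p)
                ref = best.position
            if len(chain) >= 3:
                pos = int(round(float(np.median(chain))))
                if not any(abs(pos - c.position) <= tolerance for c in confirmed):
                    confirmed.append(BorderCandidate(
                        position=pos,
                        block_sizes_supporting=cand.block_sizes_supporting,
                        min_corrected_p=p_min,
                        confirmed_sections=len(chain)))
    return sorted(confirmed, key=lambda c: c.position)
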