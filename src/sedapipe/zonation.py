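"""Stratigraphically constrained zonation.

CONISS (constrained incremental sum of squares) is agglomerative clustering
where only stratigraphically adjacent clusters may merge; at every step the
merge performed is the one whose within-cluster sum of squares (about the
cluster centroid, squared Euclidean distance) grows least.  The sequence of
dispersion increments doubles as the cost curve for deciding how many zones
are significant: the proportional dispersion reduction of the k-th split is
compared against the broken-stick expectation

    E_k = (1/n) * sum_{j=k..n} 1/j,

and zones stay significant while the observed reduction exceeds it.
``optimal_partition`` provides the exact dynamic-programming counterpart
(minimum total within-zone sum of squares over all contiguous partitions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ZonationResult",
    "coniss",
    "optimal_partition",
    "broken_stick",
    "broken_stick_expectation",
    "zonate",
    "apply_transform",
]


def apply_transform(matrix: np.ndarray, transform: str | None) -> np.ndarray:
    """'fourth_root' (default ordination transform), 'chord', or None."""
    x = np.asarray(matrix, dtype=float)
    if transform is None or transform == "none":
        return x
    if transform == "fourth_root":
        if (x < 0).any():
            raise ValueError("fourth-root transform needs non-negative data")
        return x ** 0.25
    if transform == "chord":
        norms = np.linalg.norm(x, axis=1, keepdims=True)
        return np.divide(x, norms, out=np.zeros_like(x), where=norms > 0)
    raise ValueError(f"unknown transform {transform!r}")


@dataclass
class ZonationResult:
    """Merge history, dispersion curve, and significant-zone decision."""

    n_samples: int
    merges: list = field(default_factory=list)  # dicts: step, left, right, increment
    increments: np.ndarray = None
    total_dispersion: float = 0.0
    n_significant_zones: int | None = None
    boundaries: list = field(default_factory=list)  # first sample index of zones 2..k
    boundary_ages: list | None = None

    def dispersion_at(self, k: int) -> float:
        """Total within-cluster dispersion when the tree is cut at k clusters."""
        if not 1 <= k <= self.n_samples:
            raise ValueError("k out of range")
        return float(self.increments[: self.n_samples - k].sum())

    def cut(self, k: int) -> list[int]:
        """Zone start indices (excluding 0) when cut at k contiguous zones."""
        if not 1 <= k <= self.n_samples:
            raise ValueError("k out of range")
        # replay the first n-k merges over singleton segments
        starts = list(range(self.n_samples))
        for m in self.merges[: self.n_samples - k]:
            starts.remove(m["right_start"])
        return starts[1:]


def _segment_ss(pref: np.ndarray, pref_sq: np.ndarray, i: int, j: int) -> float:
    """Within-SS of samples i..j inclusive (0-based), via prefix sums."""
    n = j - i + 1
    s = pref[j + 1] - pref[i]
    sq = pref_sq[j + 1] - pref_sq[i]
    return float(sq - s @ s / n)


def coniss(matrix, transform: str | None = None) -> ZonationResult:
    """Constrained incremental sum-of-squares clustering.

    Rows must already be in stratigraphic order.  Ties in the minimal
    increment break toward the stratigraphically older (upper) merge, so the
    result is deterministic.
    """
    x = apply_transform(matrix, transform)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")

    pref = np.vstack([np.zeros(x.shape[1]), np.cumsum(x, axis=0)])
    pref_sq = np.concatenate([[0.0], np.cumsum((x * x).sum(axis=1))])

    segments = [(i, i) for i in range(n)]  # (start, end), stratigraphic order
    ss = [0.0] * n
    merges = []
    increments = []
    while len(segments) > 1:
        best = None
        for a in range(len(segments) - 1):
            i0, _ = segments[a]
            _, j1 = segments[a + 1]
            inc = _segment_ss(pref, pref_sq, i0, j1) - ss[a] - ss[a + 1]
            if best is None or inc < best[0] - 1e-15:
                best = (inc, a)
        inc, a = best
        left, right = segments[a], segments[a + 1]
        merges.append(
            {
                "step": len(merges) + 1,
                "left_start": left[0],
                "left_end": left[1],
                "right_start": right[0],
                "right_end": right[1],
                "increment": float(inc),
            }
        )
        increments.append(inc)
        segments[a] = (left[0], right[1])
        ss[a] = _segment_ss(pref, pref_sq, left[0], right[1])
        del segments[a + 1]
        del ss[a + 1]

    res = ZonationResult(
        n_samples=n,
        merges=merges,
        increments=np.asarray(increments, dtype=float),
        total_dispersion=_segment_ss(pref, pref_sq, 0, n - 1),
    )
    return res


def optimal_partition(matrix, k: int, transform: str | None = None):
    """Exact minimum within-zone SS over contiguous partitions into k zones.

    Returns ``(boundaries, cost)`` where boundaries are the start indices of
    zones 2..k.  Dynamic programming, O(k n^2).
    """
    x = apply_transform(matrix, transform)
    n = x.shape[0]
    if not 1 <= k <= n:
        raise ValueError("k must lie in 1..n_samples")
    pref = np.vstack([np.zeros(x.shape[1]), np.cumsum(x, axis=0)])
    pref_sq = np.concatenate([[0.0], np.cumsum((x * x).sum(axis=1))])

    cost = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            for i in range(m - 1, j):
                c = cost[m - 1, i] + _segment_ss(pref, pref_sq, i, j - 1)
                if c < cost[m, j] - 1e-15:
                    cost[m, j] = c
                    back[m, j] = i
    bounds = []
    j = n
    for m in range(k, 0, -1):
        i = back[m, j]
        if i > 0:
            bounds.append(int(i))
        j = i
    return sorted(bounds), float(cost[k, n])


def broken_stick_expectation(n: int) -> np.ndarray:
    """E_k = (1/n) * sum_{j=k..n} 1/j for k = 1..n."""
    inv = 1.0 / np.arange(1, n + 1)
    return np.cumsum(inv[::-1])[::-1] / n


def broken_stick(result: ZonationResult) -> int:
    """Number of significant zones by the broken-stick comparison.

    Split k takes the record from k to k+1 zones; its observed proportional
    dispersion reduction is the corresponding merge increment divided by the
    total dispersion.  Significant zones = 1 + the number of *leading*
    splits whose reduction exceeds the broken-stick expectation.
    """
    n = result.n_samples
    total = result.total_dispersion
    if total <= 0:
        return 1
    expect = broken_stick_expectation(n)
    k_sig = 1
    for k in range(1, n):
        observed = result.increments[n - 1 - k] / total
        if observed > expect[k - 1]:
            k_sig = k + 1
        else:
            break
    return k_sig


def zonate(
    matrix, ages=None, transform: str | None = "fourth_root"
) -> ZonationResult:
    """CONISS + broken-stick significance + zone boundaries in one call."""
    res = coniss(matrix, transform=transform)
    res.n_significant_zones = broken_stick(res)
    res.boundaries = res.cut(res.n_significant_zones)
    if ages is not None:
        ages = np.asarray(ages, dtype=float)
        res.boundary_ages = [float(ages[b - 1] + ages[b]) / 2 for b in res.boundaries]
    return res
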