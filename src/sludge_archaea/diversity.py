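"""Clone-library diversity statistics.

Operational taxonomic units (OTUs) are formed from a pairwise-distance matrix
by complete-linkage agglomeration at nested similarity thresholds (98.7% ~
species, 95% ~ genus, 90% ~ family/class, 80% ~ phylum).  On the resulting
abundance vector this module computes the classic Chao1 lower-bound richness
estimate, OTU accumulation (collector's) curves, and the Pareto-Lorenz
evenness curve with its functional-organization index Fo — the combined
relative abundance of the most abundant 20% of OTUs (20% = perfect evenness,
higher = a specialized community).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skbio import DistanceMatrix

GAP_CHARS = frozenset("-.")


@dataclass
class OTUPartition:
    """A clustering of sequences into OTUs at one similarity threshold."""

    threshold: float
    otus: dict[str, list[str]]  # otu_id -> member sequence ids
    abundances: dict[str, int]  # otu_id -> member count

    @property
    def n_otus(self) -> int:
        return len(self.otus)

    def abundance_vector(self) -> list[int]:
        """Counts sorted descending (the usual rank-abundance input)."""
        return sorted(self.abundances.values(), reverse=True)


@dataclass(frozen=True)
class RichnessEstimate:
    """Observed and Chao1-estimated richness with library coverage."""

    s_obs: int
    f1: int
    f2: int
    chao1: float
    coverage: float  # 100 * s_obs / chao1


@dataclass
class LorenzCurve:
    """Pareto-Lorenz curve vertices and the Fo index (percent)."""

    x: np.ndarray  # cumulative proportion of OTUs, high-to-low abundance
    y: np.ndarray  # cumulative proportion of abundance
    fo: float


def pairwise_distances(ids: Sequence[str], aligned: Sequence[str]) -> DistanceMatrix:
    """Uncorrected p-distances with pairwise gap deletion.

    The distance between two aligned sequences is the proportion of differing
    positions over the columns where both carry a non-gap character.  All
    sequences must share the alignment length; a pair with zero comparable
    columns is an error.
    """
    if len(ids) != len(aligned):
        raise ValueError("ids and sequences must be parallel")
    n = len(aligned)
    if n == 0:
        raise ValueError("no sequences")
    length = len(aligned[0])
    if length < 1 or any(len(s) != length for s in aligned):
        raise ValueError("sequences must share a positive aligned length")
    chars = np.array([list(s.upper()) for s in aligned])
    is_gap = np.isin(chars, list(GAP_CHARS))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ~(is_gap[i] | is_gap[j])
            m = int(comparable.sum())
            if m == 0:
                raise ValueError(f"no comparable columns between {ids[i]!r} and {ids[j]!r}")
            diff = int((chars[i, comparable] != chars[j, comparable]).sum())
            d[i, j] = d[j, i] = diff / m
    return DistanceMatrix(d, ids=list(ids))


def assign_otus(dm: DistanceMatrix, threshold: float) -> OTUPartition:
    """Complete-linkage OTU assignment at a similarity threshold.

    Clusters merge greedily by smallest furthest-neighbor distance until the
    smallest inter-cluster complete-linkage distance exceeds ``1 - threshold``.
    Ties are broken by the lexicographic order of each cluster's smallest
    member id.  OTU ids are assigned by descending abundance (then smallest
    member id) as OTU1, OTU2, ...
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    cutoff = 1.0 - threshold
    ids = list(dm.ids)
    d = np.asarray(dm.data, dtype=float)
    clusters: list[list[int]] = [[i] for i in range(len(ids))]

    def complete_d(a: list[int], b: list[int]) -> float:
        return max(d[i, j] for i in a for j in b)

    def sort_key(c: list[int]) -> str:
        return min(ids[i] for i in c)

    while len(clusters) > 1:
        best: Optional[tuple[float, str, str, int, int]] = None
        for ai in range(len(clusters)):
            for bi in range(ai + 1, len(clusters)):
                dist = complete_d(clusters[ai], clusters[bi])
                ka, kb = sorted((sort_key(clusters[ai]), sort_key(clusters[bi])))
                cand = (dist, ka, kb, ai, bi)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        assert best is not None
        dist, _, _, ai, bi = best
        if dist > cutoff:
            break
        merged = sorted(clusters[ai] + clusters[bi])
        clusters = [c for k, c in enumerate(clusters) if k not in (ai, bi)]
        clusters.append(merged)

    clusters.sort(key=lambda c: (-len(c), sort_key(c)))
    otus = {f"OTU{k + 1}": sorted(ids[i] for i in c) for k, c in enumerate(clusters)}
    abundances = {otu_id: len(members) for otu_id, members in otus.items()}
    return OTUPartition(threshold=threshold, otus=otus, abundances=abundances)


def chao1(abundances: Sequence[int]) -> RichnessEstimate:
    """Classic Chao1 lower-bound richness from an OTU abundance vector.

    Chao1 = S_obs + f1^2 / (2 f2), with the f2 = 0 fallback
    S_obs + f1 (f1 - 1) / 2.  Coverage is 100 * S_obs / Chao1.
    """
    counts = [int(c) for c in abundances]
    if not counts:
        raise ValueError("empty abundance vector")
    if any(c < 1 for c in counts):
        raise ValueError("abundances must be positive integers")
    s_obs = len(counts)
    f1 = sum(1 for c in counts if c == 1)
    f2 = sum(1 for c in counts if c == 2)
    if f2 > 0:
        est = s_obs + f1 * f1 / (2.0 * f2)
    else:
        est = s_obs + f1 * (f1 - 1) / 2.0
    return RichnessEstimate(s_obs=s_obs, f1=f1, f2=f2, chao1=est,
                            coverage=100.0 * s_obs / est)


def accumulation_curve(clone_labels: Sequence[str], n_permutations: int = 1000,
                       seed: int = 0) -> np.ndarray:
    """Expected OTU count among the first k clones, for k = 1..n.

    The collector's curve: mean over random clone orderings of the number of
    distinct OTU labels seen in the first k clones.
    """
    labels = list(clone_labels)
    if not labels:
        raise ValueError("empty clone list")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    codes = np.asarray(np.unique(labels, return_inverse=True)[1])
    n = len(codes)
    n_labels = codes.max() + 1
    total = np.zeros(n)
    for _ in range(n_permutations):
        order = rng.permutation(n)
        seen = np.zeros(n_labels, dtype=bool)
        count = 0
        for k, idx in enumerate(order):
            if not seen[codes[idx]]:
                seen[codes[idx]] = True
                count += 1
            total[k] += count
    return total / n_permutations


def expected_accumulation(clone_labels: Sequence[str]) -> np.ndarray:
    """Exact analytic collector's curve (hypergeometric rarefaction).

    E[distinct OTUs among k of n clones] = S - sum_i C(n - n_i, k) / C(n, k).
    Serves as the closed-form check of :func:`accumulation_curve`.
    """
    from scipy.special import gammaln

    labels = list(clone_labels)
    _, counts = np.unique(labels, return_counts=True)
    n = len(labels)

    def log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    ks = np.arange(1, n + 1)
    out = np.empty(n, dtype=float)
    for idx, k in enumerate(ks):
        missing = 0.0
        for c in counts:
            if n - c >= k:
                missing += np.exp(log_choose(n - c, k) - log_choose(n, k))
        out[idx] = len(counts) - missing
    return out


def pareto_lorenz(abundances: Sequence[int]) -> LorenzCurve:
    """Pareto-Lorenz curve and Fo index of an OTU abundance vector.

    OTUs are ranked by descending abundance; the curve plots the cumulative
    proportion of abundance (y) against the cumulative proportion of OTUs (x).
    Fo is 100*y at x = 0.20, linearly interpolated between curve vertices when
    20% of the OTU count is not an integer.
    """
    counts = np.asarray(sorted(abundances, reverse=True), dtype=float)
    if counts.size == 0 or (counts <= 0).any():
        raise ValueError("abundances must be a nonempty positive vector")
    s = counts.size
    x = np.concatenate([[0.0], np.arange(1, s + 1) / s])
    y = np.concatenate([[0.0], np.cumsum(counts) / counts.sum()])
    fo = 100.0 * float(np.interp(0.20, x, y))
    return LorenzCurve(x=x, y=y, fo=fo)
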