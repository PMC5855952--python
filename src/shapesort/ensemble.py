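"""Structure-ensemble comparison for two alleles of one transcript.

A riboSNitch does not necessarily swap one structure for another: it can
redistribute the Boltzmann ensemble across conformational clusters.  This
module consumes dot-bracket structure samples (produced externally, e.g. by
SHAPE-directed Boltzmann sampling), clusters the pooled reference+alternate
sample by base-pair distance with k-medoids (PAM), extracts medoid
structures and per-source cluster populations, embeds the ensemble in 2-D
by classical multidimensional scaling, and quantifies the allele-induced
population shift as a total-variation distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr
from sklearn.metrics import silhouette_score

__all__ = [
    "StructureSample",
    "EnsembleMap",
    "parse_dotbracket",
    "pair_set",
    "bp_distance",
    "cluster_shared",
    "embed_2d",
    "ensemble_shift",
]


class DotBracketError(ValueError):
    """Raised on malformed dot-bracket input; carries a 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def pair_set(structure: str) -> frozenset[tuple[int, int]]:
    """Extract the base-pair set of a pseudoknot-free dot-bracket string.

    Pairs are 0-based ``(i, j)`` tuples with ``i < j``.  Raises
    :class:`DotBracketError` on unbalanced or illegal characters.
    """
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise DotBracketError(f"unmatched ')' at position {i}")
            pairs.add((stack.pop(), i))
        elif ch != ".":
            raise DotBracketError(f"illegal character {ch!r} at position {i}")
    if stack:
        raise DotBracketError(f"unmatched '(' at position {stack[-1]}")
    return frozenset(pairs)


@dataclass
class StructureSample:
    """A set of equal-length dot-bracket structures from one source.

    ``source`` tags where the sample came from (``ref``, ``alt``, or any
    condition label); it is carried through clustering so per-source cluster
    populations can be reported.
    """

    length: int
    structures: list[str]
    source: str = "ref"
    pairs: list[frozenset[tuple[int, int]]] = field(default_factory=list)

    def __post_init__(self):
        if not self.pairs:
            self.pairs = [pair_set(s) for s in self.structures]

    def __len__(self) -> int:
        return len(self.structures)


def parse_dotbracket(lines, source: str = "ref") -> StructureSample:
    """Parse an iterable of dot-bracket lines into a :class:`StructureSample`.

    Blank lines are skipped.  All structures must have equal length and
    balanced brackets; errors report the offending 1-based line number.
    """
    structures: list[str] = []
    pairs: list[frozenset[tuple[int, int]]] = []
    length: int | None = None
    for lineno, raw in enumerate(lines, start=1):
        s = raw.strip()
        if not s:
            continue
        if length is None:
            length = len(s)
        elif len(s) != length:
            raise DotBracketError(
                f"length {len(s)} != expected {length}", line=lineno
            )
        try:
            pairs.append(pair_set(s))
        except DotBracketError as exc:
            raise DotBracketError(str(exc), line=lineno) from None
        structures.append(s)
    if length is None:
        raise DotBracketError("no structures found")
    return StructureSample(length=length, structures=structures, source=source, pairs=pairs)


def bp_distance(s1, s2) -> int:
    """Base-pair distance: |symmetric difference of the two base-pair sets|.

    Accepts dot-bracket strings or precomputed pair sets.  A true metric on
    structures of equal length.
    """
    if isinstance(s1, str) or isinstance(s2, str):
        if len(s1) != len(s2):
            raise ValueError(f"length mismatch: {len(s1)} vs {len(s2)}")
        p1 = pair_set(s1) if isinstance(s1, str) else s1
        p2 = pair_set(s2) if isinstance(s2, str) else s2
    else:
        p1, p2 = s1, s2
    return len(p1 ^ p2)


def _distance_matrix(pairs: list[frozenset]) -> np.ndarray:
    n = len(pairs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = len(pairs[i] ^ pairs[j])
    return d


# ---------------------------------------------------------------------------
# k-medoids (PAM): deterministic BUILD initialization + best-improvement SWAP
# ---------------------------------------------------------------------------

def _pam_build(d: np.ndarray, k: int) -> list[int]:
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=0)))]
    while len(medoids) < k:
        nearest = d[:, medoids].min(axis=1)
        # gain of adding candidate c: sum over points of max(nearest - d[:,c], 0)
        gains = np.maximum(nearest[:, None] - d, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return medoids

def _pam_swap(d: np.ndarray, medoids: list[int], max_iter: int = 100) -> list[int]:
    n = d.shape[0]
    medoids = list(medoids)
    for _ in range(max_iter):
        cost = d[:, medoids].min(axis=1).sum()
        best = (0.0, None)
        for mi, m in enumerate(medoids):
            others = [x for x in medoids if x != m]
            base = d[:, others].min(axis=1) if others else np.full(n, np.inf)
            for c in range(n):
                if c in medoids:
                    continue
                new_cost = np.minimum(base, d[:, c]).sum()
                delta = new_cost - cost
                if delta < best[0] - 1e-12:
                    best = (delta, (mi, c))
        if best[1] is None:
            break
        mi, c = best[1]
        medoids[mi] = c
    return medoids


@dataclass
class EnsembleMap:
    """Clustered, embedded view of a pooled two-source structure ensemble."""

    distances: np.ndarray
    labels: np.ndarray          # cluster id per structure, 0..k-1
    medoids: np.ndarray         # structure index per cluster
    sources: np.ndarray         # source label per structure
    populations: dict[str, np.ndarray]  # source -> fraction per cluster
    coords: np.ndarray          # (n, 2) MDS embedding
    embedding_rho: float        # Spearman rho, embedded vs input distances
    structures: list[str]

    @property
    def k(self) -> int:
        return len(self.medoids)

    def medoid_structures(self) -> list[str]:
        return [self.structures[m] for m in self.medoids]


def cluster_shared(
    sample_ref: StructureSample,
    sample_alt: StructureSample,
    k: int | str = "auto",
    seed: int | None = None,
) -> EnsembleMap:
    """Cluster two allele ensembles in one shared conformational space.

    Structures from both sources are pooled, the pairwise base-pair distance
    matrix is computed, and PAM k-medoids partitions the pool.  With
    ``k='auto'`` the cluster count maximizes the mean silhouette over
    k in 2..6.  Because PAM is initialized by its deterministic BUILD step,
    the result does not depend on ``seed`` (kept for interface stability).
    Per-source cluster population fractions each sum to 1.
    """
    if sample_ref.length != sample_alt.length:
        raise ValueError("ref and alt samples must have equal sequence length")
    pairs = sample_ref.pairs + sample_alt.pairs
    structures = sample_ref.structures + sample_alt.structures
    sources = np.array(
        [sample_ref.source] * len(sample_ref) + [sample_alt.source] * len(sample_alt)
    )
    n = len(pairs)
    d = _distance_matrix(pairs)

    if not np.any(d > 0):
        # All structures identical: one degenerate cluster.
        labels = np.zeros(n, dtype=int)
        medoids = np.array([0])
        k_eff = 1
    else:
        if k == "auto":
            best_k, best_sil = None, -np.inf
            for kk in range(2, 7):
                if n < 2 * kk:
                    break
                med = _pam_swap(d, _pam_build(d, kk))
                lab = np.argmin(d[:, med], axis=1)
                if len(np.unique(lab)) < 2:
                    continue
                sil = silhouette_score(d, lab, metric="precomputed")
                if sil > best_sil:
                    best_k, best_sil = kk, sil
            k_eff = best_k if best_k is not None else 1
        else:
            k_eff = int(k)
            if n < 2 * k_eff:
                raise ValueError(f"pooled sample size {n} < 2k = {2 * k_eff}")
        if k_eff == 1:
            medoids = np.array([int(np.argmin(d.sum(axis=0)))])
            labels = np.zeros(n, dtype=int)
        else:
            med = _pam_swap(d, _pam_build(d, k_eff))
            med = sorted(med)
            medoids = np.array(med)
            labels = np.argmin(d[:, medoids], axis=1)

    populations = {}
    for src in dict.fromkeys(sources):  # preserves order
        mask = sources == src
        frac = np.array([(labels[mask] == c).mean() for c in range(len(medoids))])
        populations[src] = frac

    coords, rho = embed_2d(d, return_rho=True)
    return EnsembleMap(
        distances=d,
        labels=labels,
        medoids=medoids,
        sources=sources,
        populations=populations,
        coords=coords,
        embedding_rho=rho,
        structures=structures,
    )


def embed_2d(distances: np.ndarray, return_rho: bool = False):
    """Classical (Torgerson) MDS embedding of a distance matrix into 2-D.

    Double-centers the squared distances and takes the top-2 eigenpairs;
    negative eigenvalues are clipped at zero.  Optionally reports the
    Spearman correlation between embedded and input distances as a
    goodness-of-embedding diagnostic.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:2]
    lam = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(lam)
    if coords.shape[1] < 2:
        coords = np.pad(coords, ((0, 0), (0, 2 - coords.shape[1])))
    if not return_rho:
        return coords
    iu = np.triu_indices(n, k=1)
    emb = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    if len(iu[0]) >= 2 and np.ptp(d[iu]) > 0 and np.ptp(emb[iu]) > 0:
        rho = float(spearmanr(d[iu], emb[iu]).statistic)
    else:
        rho = float("nan")
    return coords, rho


def ensemble_shift(emap: EnsembleMap):
    """Per-cluster population deltas (alt − ref) and their total variation.

    TV = ½ Σ|Δ| lies in [0, 1]: 0 for identical compositions, 1 when the
    two sources occupy disjoint cluster sets.
    """
    srcs = list(emap.populations)
    if len(srcs) < 2:
        raise ValueError("ensemble_shift requires a two-source map")
    ref_src, alt_src = srcs[0], srcs[1]
    delta = emap.populations[alt_src] - emap.populations[ref_src]
    tv = 0.5 * float(np.abs(delta).sum())
    return delta, tv
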