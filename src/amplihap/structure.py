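"""Distance-based clustering, ordination, and core-set selection.

The simple-matching distance between two diploid multi-allelic
profiles averages, over comparable segments, one minus half the number
of shared alleles (with multiplicity, so a heterozygote vs a
homozygote sharing one allele scores 1/2).  Trees are built by UPGMA
(average linkage, ultrametric) or neighbour joining; branch support is
estimated by bootstrap over loci.  Principal coordinates come from
Gower double-centering of the squared distances.  Core sets maximise
allele coverage: the fraction of all observed (segment, haplotype)
pairs carried by the selected genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skbio.tree import TreeNode, nj, upgma

from .core import DistanceMatrix, GenotypeProfile

__all__ = [
    "simple_matching_distance",
    "distance_matrix",
    "build_tree",
    "bipartitions",
    "bootstrap_support",
    "pcoa",
    "CoreSetResult",
    "core_select",
]


def _pair_similarity(pa, pb) -> float:
    """Shared-allele count (0, 1 or 2, with multiplicity) over 2."""
    a1, a2 = pa
    b1, b2 = pb
    # best matching of the two unordered pairs
    m = max(
        (a1 == b1) + (a2 == b2),
        (a1 == b2) + (a2 == b1),
    )
    return m / 2.0


def simple_matching_distance(a: GenotypeProfile, b: GenotypeProfile) -> float:
    if a.segment_ids != b.segment_ids:
        raise ValueError("profiles cover different segment sets")
    sims = []
    for seg in a.segment_ids:
        ga, gb = a.genotypes[seg], b.genotypes[seg]
        if ga.is_missing or gb.is_missing:
            continue
        sims.append(_pair_similarity(ga.hap_pair, gb.hap_pair))
    if not sims:
        raise ValueError(
            f"no comparable segment between {a.profile_id} and {b.profile_id}"
        )
    return 1.0 - float(np.mean(sims))


def _locus_rows(profiles: Sequence[GenotypeProfile]) -> list[list]:
    """Per-profile list of per-locus unordered pairs (None = missing)."""
    segs = profiles[0].segment_ids
    return [[p.genotypes[s].hap_pair for s in segs] for p in profiles]


def _distance_from_rows(rows: list[list], labels: list[str]) -> DistanceMatrix:
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sims = [
                _pair_similarity(rows[i][k], rows[j][k])
                for k in range(len(rows[i]))
                if rows[i][k] is not None and rows[j][k] is not None
            ]
            if not sims:
                raise ValueError(f"no comparable locus between {labels[i]} and {labels[j]}")
            d[i, j] = d[j, i] = 1.0 - float(np.mean(sims))
    return DistanceMatrix(labels, d)


def distance_matrix(profiles: Sequence[GenotypeProfile]) -> DistanceMatrix:
    """Pairwise simple-matching distances over a panel."""
    return _distance_from_rows(_locus_rows(profiles), [p.profile_id for p in profiles])


def build_tree(dm: DistanceMatrix, method: str = "upgma") -> TreeNode:
    """UPGMA or neighbour-joining tree from a distance matrix.

    NJ branch lengths can come out negative on non-additive input;
    they are clamped to zero with the deficit moved to the adjacent
    branch (the ``neg_as_zero`` behaviour of the solver).
    """
    if method not in ("upgma", "nj"):
        raise ValueError(f"method must be 'upgma' or 'nj', got {method!r}")
    if len(dm) == 2:  # solvers need >= 3 leaves; split the edge evenly
        half = dm.matrix[0, 1] / 2
        children = [TreeNode(name=label, length=half) for label in dm.labels]
        return TreeNode(children=children)
    sk_dm = dm.to_skbio()
    if method == "upgma":
        return upgma(sk_dm)
    return nj(sk_dm, neg_as_zero=True)


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial leaf bipartitions of a tree, in canonical form.

    Each internal edge splits the leaves in two; the side not
    containing the lexicographically smallest leaf represents the
    split.  Splits of size < 2 or > n - 2 (trivial in the unrooted
    sense) are dropped, so UPGMA and NJ trees are comparable.
    """
    leaves = {t.name for t in tree.tips()}
    ref = min(leaves)
    n = len(leaves)
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = frozenset(leaves - side)
        if 2 <= len(side) <= n - 2:
            out.add(side)
    return out


def bootstrap_support(
    profiles: Sequence[GenotypeProfile],
    method: str = "nj",
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[TreeNode, dict[frozenset, float]]:
    """Tree with bootstrap support percentages on internal nodes.

    Loci (segments) are resampled with replacement ``n_boot`` times;
    the support of an internal edge is the percentage of replicate
    trees containing the same leaf bipartition.  Supports are attached
    as ``node.support`` and as internal node names, so they appear as
    labels in Newick output.  Fully reproducible for a fixed seed.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rows = _locus_rows(profiles)
    labels = [p.profile_id for p in profiles]
    n_loci = len(rows[0])
    tree = build_tree(_distance_from_rows(rows, labels), method)

    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_boot):
        idx = rng.integers(0, n_loci, size=n_loci)
        boot_rows = [[row[k] for k in idx] for row in rows]
        boot_tree = build_tree(_distance_from_rows(boot_rows, labels), method)
        for split in bipartitions(boot_tree):
            counts[split] = counts.get(split, 0) + 1

    leaves = set(labels)
    ref = min(leaves)
    supports: dict[frozenset, float] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = side if ref not in side else frozenset(leaves - side)
        if not (2 <= len(canon) <= len(leaves) - 2):
            continue
        pct = 100.0 * counts.get(canon, 0) / n_boot
        node.support = pct
        node.name = f"{pct:g}"
        supports[canon] = pct
    return tree, supports


def pcoa(dm: DistanceMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinates of a distance matrix.

    Gower-centres -D^2/2 and eigendecomposes; axes with negative
    eigenvalues (non-Euclidean residue of the distance) are dropped
    from both the coordinates and the explained-variance denominator.
    Returns the coordinates (rows = labels, columns PC1..PCm) and the
    per-axis explained-variance fractions.
    """
    d2 = dm.matrix**2
    n = len(dm)
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ d2 @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    positive = eigvals > max(1e-12, 1e-10 * abs(eigvals).max())
    eigvals, eigvecs = eigvals[positive], eigvecs[:, positive]
    coords = eigvecs * np.sqrt(eigvals)
    explained = eigvals / eigvals.sum() if eigvals.size else eigvals
    df = pd.DataFrame(
        coords,
        index=dm.labels,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return df, explained


# ---------------------------------------------------------------------------
# Core-set selection by allele coverage
# ---------------------------------------------------------------------------


@dataclass
class CoreSetResult:
    size: int
    selected: list[str]
    coverage: float


def _allele_sets(profiles: Sequence[GenotypeProfile]) -> dict[str, set]:
    out = {}
    for p in profiles:
        alleles = set()
        for seg, g in p.genotypes.items():
            if not g.is_missing:
                alleles.update((seg, h) for h in g.hap_pair)
        out[p.profile_id] = alleles
    return out


def core_select(
    profiles: Sequence[GenotypeProfile],
    sizes: Sequence[int],
    seed: int = 0,
    restarts: int = 8,
) -> list[CoreSetResult]:
    """Allele-coverage core sets for each requested size.

    Coverage of a subset S is the fraction of all observed
    (segment, haplotype) pairs carried by S.  Optimiser: greedy
    seeding followed by steepest-ascent single-swap exchange until no
    swap improves, repeated over seeded restarts with randomised
    greedy tie-breaks; the best subset wins.  Sizes are processed in
    ascending order and each size also considers extending the
    previous best set, so the coverage curve is non-decreasing.
    """
    ids = [p.profile_id for p in profiles]
    sets = _allele_sets(profiles)
    universe = set().union(*sets.values())
    if any(not (2 <= s <= len(ids)) for s in sizes):
        raise ValueError("sizes must lie in [2, number of profiles]")

    def cov(selected: Sequence[str]) -> float:
        covered = set().union(*(sets[i] for i in selected)) if selected else set()
        return len(covered) / len(universe)

    def greedy(size: int, rng) -> list[str]:
        selected: list[str] = []
        covered: set = set()
        while len(selected) < size:
            gains = {
                i: len(sets[i] - covered) for i in ids if i not in selected
            }
            best = max(gains.values())
            tied = [i for i, g in gains.items() if g == best]
            pick = tied[rng.integers(len(tied))] if len(tied) > 1 else tied[0]
            selected.append(pick)
            covered |= sets[pick]
        return selected

    def exchange(selected: list[str]) -> list[str]:
        selected = list(selected)
        improved = True
        while improved:
            improved = False
            current = cov(selected)
            best_swap, best_cov = None, current
            for out_id in selected:
                rest = [i for i in selected if i != out_id]
                for in_id in ids:
                    if in_id in selected:
                        continue
                    c = cov(rest + [in_id])
                    if c > best_cov + 1e-12:
                        best_cov, best_swap = c, (out_id, in_id)
            if best_swap:
                out_id, in_id = best_swap
                selected = [i for i in selected if i != out_id] + [in_id]
                improved = True
        return selected

    results = []
    prev_best: Optional[list[str]] = None
    for size in sorted(set(sizes)):
        candidates = []
        for r in range(restarts):
            rng = np.random.default_rng((seed, size, r))
            candidates.append(exchange(greedy(size, rng)))
        if prev_best is not None and len(prev_best) < size:
            rng = np.random.default_rng((seed, size, restarts))
            extended = list(prev_best)
            while len(extended) < size:
                gains = {
                    i: len(sets[i] - set().union(*(sets[j] for j in extended)))
                    for i in ids
                    if i not in extended
                }
                best = max(gains.values())
                tied = sorted(i for i, g in gains.items() if g == best)
                extended.append(tied[0])
            candidates.append(exchange(extended))
        best = max(candidates, key=cov)
        prev_best = best
        results.append(CoreSetResult(size, sorted(best), cov(best)))
    return results
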