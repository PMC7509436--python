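"""Haplotype reconstruction from unphased multi-SNP diploid genotypes.

Each amplicon segment carries a handful of SNPs.  An accession's
unphased genotype at the segment (one unordered base pair per SNP
site) is compatible with ``2^(h-1)`` haplotype pairs, where ``h`` is
its number of heterozygous sites.  Haplotype frequencies are estimated
by gene-counting expectation–maximisation: the E-step distributes each
accession over its compatible pairs in proportion to the
Hardy–Weinberg pair probability ``c · p(h1) p(h2)`` (``c = 2`` for
heterozygous pairs), the M-step re-estimates frequencies from the
expected haplotype counts over the ``2N`` gene copies.  The observed-
data log-likelihood is non-decreasing across iterations, and on the
short, strongly linked amplicons targeted here the deterministic EM
optimum coincides with the sampled posterior mode of MCMC phasing in
practice.

Initialisation is uniform over the compatible haplotype set, so the
procedure is fully deterministic; equally likely maximum-probability
pairs are broken toward the lexicographically smallest pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import MISSING, GenotypeProfile, Haplotype

__all__ = [
    "SiteGenotypeVector",
    "PhasingResult",
    "enumerate_compatible_pairs",
    "em_phase",
    "assign_hap_ids",
    "phase_segment",
    "collapse_genotypes",
    "GenotypeGroup",
]

MAX_HET_SITES = 20


@dataclass(frozen=True)
class SiteGenotypeVector:
    """Unphased diploid calls of one accession over one segment's SNP sites.

    ``sites`` holds one unordered base pair per SNP site (stored
    sorted), or ``None`` where the call is missing.
    """

    segment_id: str
    accession_id: str
    sites: tuple[Optional[tuple[str, str]], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "sites",
            tuple(None if s is None else tuple(sorted(s)) for s in self.sites),
        )

    @property
    def has_missing(self) -> bool:
        return any(s is None for s in self.sites)

    @property
    def n_het(self) -> int:
        return sum(s is not None and s[0] != s[1] for s in self.sites)


def enumerate_compatible_pairs(v: SiteGenotypeVector) -> list[tuple[str, str]]:
    """All unordered haplotype pairs compatible with an unphased vector.

    For ``h`` heterozygous sites there are ``max(1, 2**(h-1))`` pairs:
    the orientation at the first heterozygous site is fixed and the
    remaining ``h - 1`` sites flip freely.
    """
    if v.has_missing:
        raise ValueError(f"vector for {v.accession_id} has missing sites")
    het_idx = [i for i, s in enumerate(v.sites) if s[0] != s[1]]
    if len(het_idx) > MAX_HET_SITES:
        raise ValueError(
            f"too many heterozygous sites for enumeration ({len(het_idx)})"
        )
    base_a = [s[0] for s in v.sites]
    base_b = [s[1] for s in v.sites]
    if not het_idx:
        hap = "".join(base_a)
        return [(hap, hap)]
    pairs = []
    # first het site keeps its sorted orientation; others flip
    for bits in range(2 ** (len(het_idx) - 1)):
        a, b = base_a[:], base_b[:]
        for k, i in enumerate(het_idx[1:]):
            if (bits >> k) & 1:
                a[i], b[i] = b[i], a[i]
        pair = tuple(sorted(("".join(a), "".join(b))))
        pairs.append(pair)
    return pairs


@dataclass
class PhasingResult:
    """Converged EM state for one segment."""

    segment_id: str
    frequencies: dict[str, float]
    map_pairs: dict[str, tuple[str, str]]
    log_likelihood: float
    n_iter: int
    converged: bool
    excluded: list[str] = field(default_factory=list)


def em_phase(
    vectors: Sequence[SiteGenotypeVector],
    tol: float = 1e-8,
    max_iter: int = 1000,
    prune_below: float = 1e-12,
    restarts: int = 0,
    seed: int = 0,
) -> PhasingResult:
    """Gene-counting EM over one segment's genotype vectors.

    Accessions with a missing site are excluded from the estimation
    (their IDs are reported in ``excluded``).  Raises on empty input.

    The default start is uniform over the compatible haplotype set and
    fully deterministic.  That start can be a symmetric saddle point
    (all pairings of a multiple heterozygote tied, with no anchor to
    break them); ``restarts > 0`` additionally runs EM from that many
    seeded Dirichlet-jittered starts and keeps the highest-likelihood
    solution, which escapes such saddles while staying reproducible.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not vectors:
        raise ValueError("em_phase requires at least one genotype vector")
    if restarts:
        candidates = [
            em_phase(vectors, tol, max_iter, prune_below, restarts=0, seed=0)
        ]
        rng = np.random.default_rng(seed)
        for _ in range(restarts):
            candidates.append(
                _em_phase_once(vectors, tol, max_iter, prune_below, init_jitter=rng)
            )
        # strictly-better likelihood wins; ties keep the uniform start
        best = candidates[0]
        for cand in candidates[1:]:
            if cand.log_likelihood > best.log_likelihood + 1e-9:
                best = cand
        return best
    return _em_phase_once(vectors, tol, max_iter, prune_below, init_jitter=None)


def _em_phase_once(
    vectors: Sequence[SiteGenotypeVector],
    tol: float,
    max_iter: int,
    prune_below: float,
    init_jitter,
) -> PhasingResult:
    segment_id = vectors[0].segment_id
    usable = [v for v in vectors if not v.has_missing]
    excluded = [v.accession_id for v in vectors if v.has_missing]
    if not usable:
        raise ValueError(f"all vectors at {segment_id} have missing sites")

    per_ind_pairs = [enumerate_compatible_pairs(v) for v in usable]
    haps = sorted({h for pairs in per_ind_pairs for pair in pairs for h in pair})
    index = {h: i for i, h in enumerate(haps)}
    K, N = len(haps), len(usable)

    # pair index arrays per individual
    pair_i = [np.array([index[p[0]] for p in pairs]) for pairs in per_ind_pairs]
    pair_j = [np.array([index[p[1]] for p in pairs]) for pairs in per_ind_pairs]
    pair_c = [
        np.where(np.array([p[0] != p[1] for p in pairs]), 2.0, 1.0)
        for pairs in per_ind_pairs
    ]

    if init_jitter is None:
        p = np.full(K, 1.0 / K)
    else:
        p = init_jitter.dirichlet(np.full(K, 5.0))
        p = np.maximum(p, 1e-6)
        p /= p.sum()
    loglik = -np.inf
    n_iter = 0
    converged = False
    weights: list[np.ndarray] = [np.empty(0)] * N
    for n_iter in range(1, max_iter + 1):
        counts = np.zeros(K)
        new_loglik = 0.0
        for ind in range(N):
            w = pair_c[ind] * p[pair_i[ind]] * p[pair_j[ind]]
            total = w.sum()
            if total <= 0:  # degenerate: fall back to uniform over pairs
                w = np.ones_like(w)
                total = w.sum()
                new_loglik += -np.inf
            else:
                new_loglik += np.log(total)
            w /= total
            weights[ind] = w
            np.add.at(counts, pair_i[ind], w)
            np.add.at(counts, pair_j[ind], w)
        if np.isfinite(loglik) and new_loglik < loglik - 1e-9:
            raise AssertionError(
                f"EM log-likelihood decreased at iteration {n_iter}: "
                f"{loglik} -> {new_loglik}"
            )
        new_p = counts / (2.0 * N)
        delta = np.max(np.abs(new_p - p))
        p = new_p
        loglik = new_loglik
        if delta < tol:
            converged = True
            break

    # MAP pair per accession: highest posterior weight, ties -> smallest pair
    map_pairs = {}
    for ind, v in enumerate(usable):
        w = weights[ind]
        best = np.flatnonzero(w >= w.max() - 1e-12)
        map_pairs[v.accession_id] = min(per_ind_pairs[ind][k] for k in best)

    frequencies = {h: float(p[index[h]]) for h in haps if p[index[h]] > prune_below}
    total = sum(frequencies.values())
    frequencies = {h: f / total for h, f in frequencies.items()}
    return PhasingResult(
        segment_id=segment_id,
        frequencies=frequencies,
        map_pairs=map_pairs,
        log_likelihood=float(loglik),
        n_iter=n_iter,
        converged=converged,
        excluded=excluded,
    )


def assign_hap_ids(result: PhasingResult) -> tuple[list[Haplotype], dict[str, int]]:
    """Numeric haplotype IDs 1..k in descending frequency order.

    Ties are broken by lexicographic sequence order, so the numbering
    is deterministic.
    """
    ordered = sorted(result.frequencies.items(), key=lambda kv: (-kv[1], kv[0]))
    mapping = {seq: i + 1 for i, (seq, _) in enumerate(ordered)}
    haplotypes = [
        Haplotype(result.segment_id, hap_id, seq) for seq, hap_id in mapping.items()
    ]
    return haplotypes, mapping


def phase_segment(
    vectors: Sequence[SiteGenotypeVector],
    tol: float = 1e-8,
    max_iter: int = 1000,
    restarts: int = 0,
    seed: int = 0,
) -> tuple[PhasingResult, list[Haplotype], dict[str, Optional[tuple[int, int]]]]:
    """EM-phase one segment and translate MAP pairs to numeric ID pairs.

    Returns the raw EM result, the numbered haplotypes, and per
    accession the canonical hap-ID pair (``None`` where the segment was
    missing).
    """
    result = em_phase(
        vectors, tol=tol, max_iter=max_iter, restarts=restarts, seed=seed
    )
    haplotypes, mapping = assign_hap_ids(result)
    id_pairs: dict[str, Optional[tuple[int, int]]] = {}
    for v in vectors:
        if v.accession_id in result.map_pairs:
            a, b = result.map_pairs[v.accession_id]
            id_pairs[v.accession_id] = tuple(sorted((mapping[a], mapping[b])))
        else:
            id_pairs[v.accession_id] = MISSING
    return result, haplotypes, id_pairs


@dataclass
class GenotypeGroup:
    """An equivalence class of accessions with structurally identical profiles."""

    group_id: int
    profile_ids: list[str]
    representative: str

    @property
    def size(self) -> int:
        return len(self.profile_ids)


def collapse_genotypes(profiles: Sequence[GenotypeProfile]) -> list[GenotypeGroup]:
    """Collapse accessions into distinct genotypes.

    Profiles are identical when every canonical haplotype pair matches
    exactly (a missing segment matches only a missing segment).  Groups
    are numbered by descending size, ties by first-accession order; the
    representative is the first member encountered.
    """
    if not profiles:
        return []
    segment_ids = profiles[0].segment_ids
    for p in profiles:
        if p.segment_ids != segment_ids:
            raise ValueError(f"profile {p.profile_id} covers a different segment set")
    buckets: dict[tuple, list[str]] = {}
    first_seen: dict[tuple, int] = {}
    for i, p in enumerate(profiles):
        key = p.key(segment_ids)
        buckets.setdefault(key, []).append(p.profile_id)
        first_seen.setdefault(key, i)
    ordered = sorted(buckets, key=lambda k: (-len(buckets[k]), first_seen[k]))
    return [
        GenotypeGroup(i + 1, buckets[key], buckets[key][0])
        for i, key in enumerate(ordered)
    ]
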