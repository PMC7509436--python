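"""Probability-of-identity statistics and the minimal fingerprinting set.

For one multi-allelic locus with allele frequencies ``p_i`` under
Hardy–Weinberg equilibrium:

* ``PI = sum(p_i^4) + sum_{i<j} (2 p_i p_j)^2`` — probability that two
  random individuals share their genotype;
* ``PI_sib = 0.25 + 0.5 a2 + 0.5 a2^2 - 0.25 a4`` with
  ``a_k = sum(p_i^k)`` — the same probability for two full siblings;
* per-genotype match probabilities against a random individual, a
  parent/offspring, and a sibling.

Multi-locus values multiply across unlinked segments, so the
cumulative products trace the discrimination power gained as segments
are added (conventionally in descending PIC order).  The capacity rule
converts a cumulative PI into the largest population size in which all
pairwise comparisons stay jointly reliable at level alpha:
``max n such that n (n - 1) / 2 * PI <= alpha`` (a birthday bound on
the expected number of colliding pairs).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import FrequencyTable, GenotypeProfile, SegmentGenotype

__all__ = [
    "pi_random",
    "pi_sib",
    "genotype_match_probs",
    "profile_match_probs",
    "capacity",
    "cumulative_discrimination",
    "minimal_marker_set",
    "fingerprint_code",
    "MatchProbs",
]


def _power_sums(freqs: Mapping[int, float], upto: int = 4) -> list[float]:
    p = np.array(list(freqs.values()), dtype=float)
    return [float(np.sum(p**k)) for k in range(upto + 1)]


def pi_random(freqs: Mapping[int, float]) -> float:
    """Probability two random HWE individuals have identical genotypes."""
    _, _, a2, _, a4 = _power_sums(freqs)
    # sum p^4 + sum_{i<j} 4 p_i^2 p_j^2 = 2 a2^2 - a4
    return 2.0 * a2**2 - a4


def pi_sib(freqs: Mapping[int, float]) -> float:
    """Probability two full siblings have identical genotypes."""
    _, _, a2, _, a4 = _power_sums(freqs)
    return 0.25 + 0.5 * a2 + 0.5 * a2**2 - 0.25 * a4


@dataclass(frozen=True)
class MatchProbs:
    """Probability that a given genotype is matched by a random
    individual, a parent/offspring, or a full sibling."""

    random: float
    par_off: float
    sib: float


def genotype_match_probs(
    g: SegmentGenotype, freqs: Mapping[int, float]
) -> MatchProbs:
    """Per-genotype match probabilities at one segment.

    Homozygote (i,i): random ``p_i^2``; parent/offspring ``p_i`` (the
    relative is known to carry one copy of i and must carry i again on
    the other chromosome drawn from the population); sibling
    ``((1 + p_i) / 2)^2``.  Heterozygote (i,j): random ``2 p_i p_j``;
    parent/offspring ``(p_i + p_j) / 2``; sibling
    ``(1 + p_i + p_j + 2 p_i p_j) / 4``.
    """
    if g.is_missing:
        raise ValueError("genotype is missing")
    i, j = g.hap_pair
    for h in (i, j):
        if h not in freqs:
            raise ValueError(f"allele {h} absent from frequency table")
    pi_, pj = freqs[i], freqs[j]
    if i == j:
        return MatchProbs(pi_**2, pi_, ((1 + pi_) / 2) ** 2)
    return MatchProbs(
        2 * pi_ * pj, (pi_ + pj) / 2, (1 + pi_ + pj + 2 * pi_ * pj) / 4
    )


def profile_match_probs(
    profile: GenotypeProfile, table: FrequencyTable
) -> MatchProbs:
    """Multi-locus match probabilities: products over non-missing segments."""
    r = po = s = 1.0
    for seg in table.segment_ids:
        g = profile.genotypes[seg]
        if g.is_missing:
            continue
        m = genotype_match_probs(g, table[seg])
        r *= m.random
        po *= m.par_off
        s *= m.sib
    return MatchProbs(r, po, s)


def capacity(pi_value: float, alpha: float = 0.05) -> int:
    """Largest n with ``n (n - 1) / 2 * pi_value <= alpha``.

    The bound keeps the expected number of identical pairs among n
    individuals below alpha, so all pairwise identifications remain
    jointly reliable.  Always at least 1 (a single individual has no
    pair to collide with).
    """
    if not (0 < pi_value <= 1):
        raise ValueError("pi_value must be in (0, 1]")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    limit = alpha / pi_value
    # float guess, then exact integer adjustment
    n = max(1, int((1 + math.sqrt(1 + 8 * limit)) / 2))
    while n * (n - 1) / 2 > limit:
        n -= 1
    while (n + 1) * n / 2 <= limit:
        n += 1
    return max(n, 1)


def cumulative_discrimination(
    profiles: Sequence[GenotypeProfile],
    table: FrequencyTable,
    segment_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Running PI / PI_sib products and distinct-genotype counts.

    ``segment_order`` defaults to descending PIC.  Row m describes the
    prefix of the first m segments: cumulative products of the
    per-segment PI and PI_sib, and the number of distinct genotype
    classes when profiles are compared on that prefix only.
    """
    from .diversity import pic  # local import to avoid a cycle

    if segment_order is None:
        segment_order = sorted(
            table.segment_ids, key=lambda s: (-pic(table[s]), s)
        )
    if sorted(segment_order) != sorted(table.segment_ids):
        raise ValueError("segment_order must be a permutation of the table's segments")
    rows = []
    cum_pi = cum_sib = 1.0
    for m, seg in enumerate(segment_order, start=1):
        cum_pi *= pi_random(table[seg])
        cum_sib *= pi_sib(table[seg])
        prefix = segment_order[:m]
        distinct = len({p.key(prefix) for p in profiles})
        rows.append((seg, m, cum_pi, cum_sib, distinct))
    return pd.DataFrame(
        rows,
        columns=["segment_id", "n_segments", "cum_pi", "cum_pi_sib", "n_distinct"],
    )


def minimal_marker_set(
    profiles: Sequence[GenotypeProfile],
    segment_order: Optional[Sequence[str]] = None,
) -> tuple[int, list[tuple[str, ...]]]:
    """All minimum-cardinality segment subsets separating every profile.

    Exact search over subset sizes s = 1, 2, ...; within a size,
    subsets are enumerated in the order induced by ``segment_order``
    (default: input order), so the result order is deterministic.  A
    subset qualifies when restricting every profile to it leaves all
    profiles pairwise distinct.  Subsets whose single-segment distinct
    counts cannot multiply up to the number of profiles are pruned.

    ``profiles`` should already be collapsed to distinct genotypes;
    raises if even the full segment set cannot separate them.
    """
    segs = list(segment_order) if segment_order else list(profiles[0].segment_ids)
    n = len(profiles)
    if len({p.key(segs) for p in profiles}) < n:
        raise ValueError("indistinguishable profiles present")
    counts = {s: len({p.key([s]) for p in profiles}) for s in segs}
    for size in range(1, len(segs) + 1):
        found = []
        for subset in itertools.combinations(segs, size):
            bound = 1
            for s in subset:
                bound *= counts[s]
            if bound < n:
                continue
            if len({p.key(subset) for p in profiles}) == n:
                found.append(subset)
        if found:
            return size, found
    raise AssertionError("unreachable: full set separates profiles")


def fingerprint_code(profile: GenotypeProfile, subset: Sequence[str]) -> str:
    """Barcode string ``SEGk:i/j;...`` over the given segments, in order."""
    tokens = []
    for seg in subset:
        g = profile.genotypes.get(seg)
        if g is None or g.is_missing:
            raise ValueError(f"profile {profile.profile_id} missing segment {seg}")
        a, b = g.hap_pair
        tokens.append(f"{seg}:{a}/{b}")
    return ";".join(tokens)
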