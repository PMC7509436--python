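"""Pairwise kinship analysis: DSN, clone/somatic classification,
candidate parent–offspring detection, and parentage non-exclusion.

The differential segment number (DSN) of two genotype profiles is the
count of segments at which their canonical haplotype pairs differ.
DSN 0 marks a clone or synonym; a small DSN (default 1–3) marks a
putative somatic variant (e.g. a loss-of-heterozygosity at a single
segment); unrelated lineages in this system sit at DSN >= 4.  Two
distinct non-somatic genotypes that share at least one haplotype at
*every* segment are candidate parent–offspring pairs — the exact
Mendelian sharing rule, with no tolerance for genotyping error.

Non-exclusion probabilities quantify the power of the segment panel in
parentage testing: the probability that a random unrelated candidate
is NOT excluded as parent of a random offspring, with the second
parent known (P1), with no parent known (P2), or as one of a candidate
parent pair (P3).  They are computed by exact enumeration over
genotype configurations under Hardy–Weinberg equilibrium and Mendelian
segregation, and multiply across unlinked loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .core import DistanceMatrix, FrequencyTable, GenotypeProfile

__all__ = [
    "dsn",
    "dsn_matrix",
    "PairClass",
    "classify_pairs",
    "candidate_parent_offspring",
    "nonexclusion",
    "cumulative_nonexclusion",
    "SCENARIOS",
]

SCENARIOS = ("one_parent_known", "no_parent_known", "parent_pair")
DEFAULT_SOMATIC_THRESHOLD = 3


def dsn(a: GenotypeProfile, b: GenotypeProfile) -> tuple[int, int]:
    """Differential segment number between two profiles.

    Returns ``(n_differing, n_skipped)``; segments missing in either
    profile are skipped and counted in ``n_skipped``.
    """
    if a.segment_ids != b.segment_ids:
        raise ValueError("profiles cover different segment sets")
    differing = skipped = 0
    for seg in a.segment_ids:
        ga, gb = a.genotypes[seg], b.genotypes[seg]
        if ga.is_missing or gb.is_missing:
            skipped += 1
        elif ga.hap_pair != gb.hap_pair:
            differing += 1
    return differing, skipped


def dsn_matrix(
    profiles: Sequence[GenotypeProfile],
) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Pairwise DSN matrix plus the matrix of skipped-segment counts."""
    n = len(profiles)
    d = np.zeros((n, n))
    sk = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dij, sij = dsn(profiles[i], profiles[j])
            d[i, j] = d[j, i] = dij
            sk[i, j] = sk[j, i] = sij
    labels = [p.profile_id for p in profiles]
    return DistanceMatrix(labels, d), DistanceMatrix(labels, sk)


@dataclass(frozen=True)
class PairClass:
    id_a: str
    id_b: str
    dsn: int
    label: str  # identical | somatic_variant | candidate_parent_offspring | unrelated


def classify_pairs(
    dm: DistanceMatrix, somatic_threshold: int = DEFAULT_SOMATIC_THRESHOLD
) -> list[PairClass]:
    """Tier each pair by DSN: 0 identical, 1..threshold somatic variant,
    above threshold unrelated (pending the allele-sharing parentage test)."""
    out = []
    for i in range(len(dm)):
        for j in range(i + 1, len(dm)):
            d = int(dm.matrix[i, j])
            if d == 0:
                label = "identical"
            elif d <= somatic_threshold:
                label = "somatic_variant"
            else:
                label = "unrelated"
            out.append(PairClass(dm.labels[i], dm.labels[j], d, label))
    return out


def _shares_haplotype_everywhere(a: GenotypeProfile, b: GenotypeProfile) -> bool:
    for seg in a.segment_ids:
        ga, gb = a.genotypes[seg], b.genotypes[seg]
        if ga.is_missing or gb.is_missing:
            continue  # a failed amplicon cannot exclude
        if not set(ga.hap_pair) & set(gb.hap_pair):
            return False
    return True


def candidate_parent_offspring(
    profiles: Sequence[GenotypeProfile],
    somatic_threshold: int = DEFAULT_SOMATIC_THRESHOLD,
    multiplicities: Optional[Mapping[str, int]] = None,
) -> tuple[list[PairClass], nx.Graph]:
    """Candidate parent–offspring pairs among collapsed profiles.

    A pair qualifies when its DSN exceeds the somatic threshold (so it
    is not a clone or somatic variant) and the two canonical pairs
    intersect at every segment.  Edges are undirected: which member is
    the parent is unknowable from genotypes alone.  Node attribute
    ``multiplicity`` records clone-group sizes when provided.
    """
    graph = nx.Graph()
    for p in profiles:
        mult = multiplicities.get(p.profile_id, 1) if multiplicities else 1
        graph.add_node(p.profile_id, multiplicity=mult)
    pairs = []
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            a, b = profiles[i], profiles[j]
            d, _ = dsn(a, b)
            if d > somatic_threshold and _shares_haplotype_everywhere(a, b):
                pairs.append(
                    PairClass(a.profile_id, b.profile_id, d, "candidate_parent_offspring")
                )
                graph.add_edge(a.profile_id, b.profile_id, dsn=d)
    return pairs, graph


# ---------------------------------------------------------------------------
# Parentage non-exclusion by exact enumeration
# ---------------------------------------------------------------------------


def _candidate_stats(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate all HWE candidate genotypes once.

    Returns ``S1[a] = P(candidate carries allele a)`` and
    ``T[a, b] = P(candidate carries both a and b)``, accumulated over
    the full ordered genotype grid (each ordered pair (x, y) with
    probability ``p_x p_y``).
    """
    k = len(p)
    gp = np.outer(p, p)  # ordered genotype probabilities
    S1 = np.zeros(k)
    T = np.zeros((k, k))
    for x in range(k):
        for y in range(k):
            prob = gp[x, y]
            carried = {x, y}
            for a in carried:
                S1[a] += prob
            for a in carried:
                for b in carried:
                    T[a, b] += prob
    return S1, T


def nonexclusion(freqs: Mapping[int, float], scenario: str) -> float:
    """Per-locus non-exclusion probability for one scenario.

    ``one_parent_known``: the true second parent is known; a random
    candidate is not excluded as the other parent when the offspring's
    alleles can be split consistently between the known parent and the
    candidate.  ``no_parent_known``: the candidate is not excluded
    when it shares at least one allele with the offspring.
    ``parent_pair``: two random candidates are not excluded as the
    parent pair when the offspring's two alleles can be assigned one
    to each.  All averages are over HWE genotypes and Mendelian
    transmission, computed by exact enumeration.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    p = np.array(list(freqs.values()), dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or np.any(p <= 0):
        raise ValueError("frequencies must be positive and sum to 1")
    k = len(p)
    if scenario == "parent_pair" and k > 40:
        raise ValueError("enumeration too large (> 40 alleles) for parent_pair")
    if k == 1:
        return 1.0
    S1, T = _candidate_stats(p)

    ne = 0.0
    if scenario == "no_parent_known":
        # offspring O ~ HWE; candidate shares >= 1 allele with O
        for a in range(k):
            for b in range(k):
                p_o = p[a] * p[b]
                share = S1[a] if a == b else S1[a] + S1[b] - T[a, b]
                ne += p_o * share
    elif scenario == "one_parent_known":
        # known parent M=(m1,m2) ~ HWE transmits m (1/2 each);
        # other allele f ~ population; O = (m, f).
        # Candidate C is compatible as second parent iff
        # f in C, or (f in M and m in C).
        for m1 in range(k):
            for m2 in range(k):
                p_m = p[m1] * p[m2]
                for m in (m1, m2):
                    for f in range(k):
                        p_conf = p_m * 0.5 * p[f]
                        if f in (m1, m2):
                            ok = S1[f] + S1[m] - T[f, m] if m != f else S1[f]
                        else:
                            ok = S1[f]
                        ne += p_conf * ok
    else:  # parent_pair
        # offspring O = (a, b) ~ HWE; candidates C1, C2 independent HWE;
        # pair not excluded iff (a in C1 and b in C2) or vice versa
        for a in range(k):
            for b in range(k):
                p_o = p[a] * p[b]
                if a == b:
                    ok = S1[a] * S1[a]
                else:
                    e1 = S1[a] * S1[b]
                    e2 = S1[b] * S1[a]
                    both = T[a, b] * T[a, b]  # a,b in C1 AND a,b in C2
                    ok = e1 + e2 - both
                ne += p_o * ok
    return float(ne)


def cumulative_nonexclusion(table: FrequencyTable, scenario: str) -> float:
    """Panel-wide non-exclusion: product of per-segment values."""
    out = 1.0
    for seg in table.segment_ids:
        out *= nonexclusion(table[seg], scenario)
    return out
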