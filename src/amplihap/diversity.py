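"""Per-segment diversity statistics over haplotype-based genotypes.

Each segment is a multi-allelic locus whose alleles are haplotypes.
With haplotype relative frequencies ``p_i`` over ``n`` counted gene
copies:

* haplotype diversity (Nei's gene diversity)
  ``Hd = 1 - sum(p_i^2)``, or the unbiased sample version
  ``(n / (n - 1)) * (1 - sum(p_i^2))``;
* polymorphic information content
  ``PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2``;
* observed heterozygosity ``Ho`` = fraction of non-missing diploid
  genotypes with two distinct haplotype IDs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import FrequencyTable, GenotypeProfile, Segment
from .phasing import collapse_genotypes

__all__ = [
    "allele_frequencies",
    "frequency_table",
    "haplotype_diversity",
    "pic",
    "observed_heterozygosity",
    "snp_mafs",
    "summarize_segments",
]


def allele_frequencies(
    profiles: Sequence[GenotypeProfile], segment_id: str
) -> tuple[dict[int, float], int]:
    """Haplotype frequencies at one segment; each non-missing diploid adds 2 copies."""
    counts: dict[int, int] = {}
    n_copies = 0
    for p in profiles:
        g = p.genotypes[segment_id]
        if g.is_missing:
            continue
        for h in g.hap_pair:
            counts[h] = counts.get(h, 0) + 1
        n_copies += 2
    if n_copies == 0:
        raise ValueError(f"all profiles missing at segment {segment_id}")
    return {h: c / n_copies for h, c in sorted(counts.items())}, n_copies


def frequency_table(
    profiles: Sequence[GenotypeProfile], segment_ids: Optional[Sequence[str]] = None
) -> FrequencyTable:
    if segment_ids is None:
        segment_ids = profiles[0].segment_ids
    freqs, n_copies = {}, {}
    for seg in segment_ids:
        freqs[seg], n_copies[seg] = allele_frequencies(profiles, seg)
    return FrequencyTable(freqs, n_copies)


def haplotype_diversity(
    freqs: Mapping[int, float], n_copies: Optional[int] = None, unbiased: bool = True
) -> float:
    """Nei's gene diversity; unbiased (n/(n-1)) correction by default."""
    p = np.array(list(freqs.values()), dtype=float)
    hd = 1.0 - float(np.sum(p**2))
    if not unbiased:
        return hd
    if n_copies is None or n_copies < 2:
        raise ValueError("unbiased Hd requires n_copies >= 2")
    return n_copies / (n_copies - 1) * hd


def pic(freqs: Mapping[int, float]) -> float:
    """Polymorphic information content (Botstein's measure)."""
    p = np.array(list(freqs.values()), dtype=float)
    sum_p2 = float(np.sum(p**2))
    sum_p4 = float(np.sum(p**4))
    # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4
    return 1.0 - sum_p2 - (sum_p2**2 - sum_p4)


def observed_heterozygosity(
    profiles: Sequence[GenotypeProfile], segment_id: str
) -> float:
    genos = [p.genotypes[segment_id] for p in profiles]
    present = [g for g in genos if not g.is_missing]
    if not present:
        raise ValueError(f"all profiles missing at segment {segment_id}")
    return sum(g.is_heterozygous for g in present) / len(present)


def snp_mafs(
    haplotypes: Mapping[int, str], freqs: Mapping[int, float]
) -> list[float]:
    """Per-SNP minor allele frequencies implied by haplotype frequencies.

    Site ``s``'s base frequencies are the summed frequencies of the
    haplotypes carrying each base; the MAF is one minus the largest.
    """
    seqs = {h: haplotypes[h] for h in freqs}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("haplotype sequences differ in length")
    (length,) = lengths
    mafs = []
    for site in range(length):
        base_freq: dict[str, float] = {}
        for h, f in freqs.items():
            b = seqs[h][site]
            base_freq[b] = base_freq.get(b, 0.0) + f
        mafs.append(1.0 - max(base_freq.values()))
    return mafs


@dataclass
class SegmentDiversity:
    segment_id: str
    n_copies: int
    k: int
    Hd: float
    Ho: float
    PIC: float


def summarize_segments(
    profiles: Sequence[GenotypeProfile],
    segments: Optional[Sequence[Segment]] = None,
    on_collapsed: bool = False,
    unbiased: bool = True,
) -> pd.DataFrame:
    """Per-segment diversity table plus unweighted column means and SDs.

    With ``on_collapsed`` the statistics are computed over the distinct
    genotypes only (one representative per clone group), the
    appropriate sample when clones would otherwise re-count the same
    genome.  The last two rows hold the unweighted mean and SD across
    segments.
    """
    if on_collapsed:
        groups = collapse_genotypes(profiles)
        by_id = {p.profile_id: p for p in profiles}
        profiles = [by_id[g.representative] for g in groups]
    segment_ids = (
        [s.segment_id for s in segments] if segments else profiles[0].segment_ids
    )
    rows = []
    for seg in segment_ids:
        freqs, n_copies = allele_frequencies(profiles, seg)
        rows.append(
            SegmentDiversity(
                segment_id=seg,
                n_copies=n_copies,
                k=len(freqs),
                Hd=haplotype_diversity(freqs, n_copies, unbiased=unbiased),
                Ho=observed_heterozygosity(profiles, seg),
                PIC=pic(freqs),
            )
        )
    df = pd.DataFrame([vars(r) for r in rows]).set_index("segment_id")
    stats = df.agg(["mean", "std"])
    stats.index = ["Mean", "SD"]
    return pd.concat([df, stats])
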