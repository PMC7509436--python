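"""SNP extraction from multiple alignments of diploid IUPAC consensus sequences.

Each consensus sequence encodes an unphased diploid: a plain base is a
homozygous site, a two-base IUPAC ambiguity code a heterozygous one.
A column of the alignment is a SNP site when, after expanding every
sample's symbol to its allele pair, at least two distinct bases occur
among the non-missing samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

__all__ = ["SnpSite", "extract_snps", "verification_rate", "expand_iupac", "merge_iupac"]

#: symbol -> unordered diploid base pair; N and gaps are missing.
#: Three/four-allele codes (B/D/H/V) are treated as missing: a diploid
#: cannot carry three alleles, so such calls are upstream noise.
IUPAC_PAIR = {
    "A": ("A", "A"),
    "C": ("C", "C"),
    "G": ("G", "G"),
    "T": ("T", "T"),
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "M": ("A", "C"),
    "K": ("G", "T"),
    "W": ("A", "T"),
    "S": ("C", "G"),
}

_PAIR_CODE = {frozenset(v): k for k, v in IUPAC_PAIR.items()}


def expand_iupac(symbol: str) -> Optional[tuple[str, str]]:
    """Expand one alignment symbol to its sorted diploid base pair, or None if missing."""
    return IUPAC_PAIR.get(symbol.upper())


def merge_iupac(base_a: str, base_b: str) -> str:
    """The consensus symbol of a diploid carrying ``base_a`` and ``base_b``."""
    if base_a not in "ACGT" or base_b not in "ACGT":
        raise ValueError(f"bases must be A/C/G/T, got {base_a!r}/{base_b!r}")
    return _PAIR_CODE[frozenset((base_a, base_b))]


@dataclass
class SnpSite:
    """One polymorphic alignment column with per-sample diploid calls."""

    column: int
    alleles: frozenset[str]
    calls: dict[str, Optional[tuple[str, str]]]
    segment_id: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.alleles) < 2 or self.alleles - set("ACGT"):
            raise ValueError(f"SNP site needs >=2 alleles from A/C/G/T, got {self.alleles}")


def extract_snps(
    alignment: Mapping[str, str],
    segment_id: Optional[str] = None,
    max_gap_fraction: float = 0.5,
) -> list[SnpSite]:
    """Scan an alignment for SNP sites.

    Samples with ``N`` or a gap at a column are MISSING there; columns
    gapped in more than ``max_gap_fraction`` of samples are skipped
    entirely (a guard for degenerate inputs — the target amplicons are
    indel-free).  The site set is invariant to sample order.
    """
    if not alignment:
        return []
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) > 1:
        raise ValueError(f"sequences differ in length: {sorted(lengths)}")
    (length,) = lengths
    samples = list(alignment)
    sites: list[SnpSite] = []
    for col in range(length):
        symbols = {s: alignment[s][col].upper() for s in samples}
        n_gap = sum(sym == "-" for sym in symbols.values())
        if n_gap > max_gap_fraction * len(samples):
            continue
        calls = {s: expand_iupac(sym) for s, sym in symbols.items()}
        observed = {b for pair in calls.values() if pair is not None for b in pair}
        if len(observed) >= 2:
            sites.append(SnpSite(col, frozenset(observed), calls, segment_id))
    return sites


def snp_table(sites: list[SnpSite]) -> pd.DataFrame:
    """Tabular view of SNP sites: one row per site, one call column per sample."""
    if not sites:
        return pd.DataFrame(columns=["segment_id", "column", "alleles"])
    samples = list(sites[0].calls)
    rows = []
    for site in sites:
        row = {
            "segment_id": site.segment_id,
            "column": site.column,
            "alleles": "/".join(sorted(site.alleles)),
        }
        for s in samples:
            pair = site.calls[s]
            row[s] = "." if pair is None else "".join(sorted(pair))
        rows.append(row)
    return pd.DataFrame(rows)


def verification_rate(n_predicted: int, n_confirmed: int) -> float:
    """Fraction of in-silico predicted SNPs confirmed by re-sequencing."""
    if n_predicted <= 0:
        raise ValueError("n_predicted must be positive")
    if not (0 <= n_confirmed <= n_predicted):
        raise ValueError("need 0 <= n_confirmed <= n_predicted")
    return n_confirmed / n_predicted
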