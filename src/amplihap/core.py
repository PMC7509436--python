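"""Domain types for haplotype-based amplicon fingerprinting.

An accession's genotype is summarised per amplicon *segment* as an
unordered pair of haplotype IDs.  A segment is a short PCR amplicon
containing several SNPs and is treated as a single multi-allelic locus;
each haplotype (the phased allele combination across the segment's SNP
sites) acts as one allele of that locus.  Phase *between* segments is
never used, so haplotype pairs are stored unordered in canonical
(numerically sorted) order.

Missing data is a segment-level state: either the whole amplicon was
genotyped or it failed, never a single allele of the pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "Segment",
    "Haplotype",
    "SegmentGenotype",
    "GenotypeProfile",
    "Accession",
    "FrequencyTable",
    "DistanceMatrix",
    "validate_profile",
]

#: sentinel for a failed amplicon (no genotype at that segment)
MISSING = None

# peak-ratio thresholds for calling a secondary base heterozygous;
# duplicated (2-copy) amplicons dilute the minor allele signal, hence
# the lower threshold there
DEFAULT_THRESHOLD_SINGLE = 0.50
DEFAULT_THRESHOLD_DUP = 0.30


@dataclass(frozen=True)
class Segment:
    """One genotyping amplicon treated as a multi-allelic locus.

    Parameters
    ----------
    segment_id : str
        Short label, e.g. ``"SEG9"``.
    amplicon_length : int
        Length of the amplified region in base pairs (per copy).
    copy_number : int
        1 for unique amplicons, 2 for amplicons hitting a duplicated
        (near-identical, adjacent) genomic region.  Duplicated segments
        are genotyped as one composite diploid locus; the copy number
        only selects the heterozygote peak-ratio threshold.
    het_ratio_threshold : float, optional
        Secondary/primary peak signal ratio above which a secondary
        base is called heterozygous.  Defaults to 0.50 for single-copy
        and 0.30 for duplicated segments.
    """

    segment_id: str
    amplicon_length: int
    copy_number: int = 1
    chrom: Optional[str] = None
    het_ratio_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if self.amplicon_length <= 0:
            raise ValueError(f"amplicon_length must be positive, got {self.amplicon_length}")
        if self.copy_number not in (1, 2):
            raise ValueError(f"copy_number must be 1 or 2, got {self.copy_number}")
        if self.het_ratio_threshold is None:
            default = (
                DEFAULT_THRESHOLD_SINGLE if self.copy_number == 1 else DEFAULT_THRESHOLD_DUP
            )
            object.__setattr__(self, "het_ratio_threshold", default)
        if not (0 < self.het_ratio_threshold <= 1):
            raise ValueError("het_ratio_threshold must be in (0, 1]")


@dataclass(frozen=True)
class Haplotype:
    """A segment allele: the phased base string over the segment's SNP sites."""

    segment_id: str
    hap_id: int
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.hap_id < 1:
            raise ValueError("hap_id must be a positive integer")
        if self.sequence is not None and set(self.sequence) - set("ACGT"):
            raise ValueError(f"haplotype sequence must be over A/C/G/T: {self.sequence!r}")


def canonical_pair(pair):
    """Return the unordered haplotype pair in canonical (sorted) order."""
    if pair is MISSING:
        return MISSING
    a, b = pair
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class SegmentGenotype:
    """Unordered haplotype-ID pair of one accession at one segment."""

    segment_id: str
    hap_pair: Optional[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.hap_pair is not MISSING:
            a, b = self.hap_pair
            if not (isinstance(a, (int, np.integer)) and isinstance(b, (int, np.integer))):
                raise ValueError(f"hap ids must be integers, got {self.hap_pair!r}")
            if a < 1 or b < 1:
                raise ValueError("hap ids must be positive")
            object.__setattr__(self, "hap_pair", canonical_pair((int(a), int(b))))

    @property
    def is_missing(self) -> bool:
        return self.hap_pair is MISSING

    @property
    def is_heterozygous(self) -> bool:
        return self.hap_pair is not MISSING and self.hap_pair[0] != self.hap_pair[1]


@dataclass
class GenotypeProfile:
    """One segment genotype per declared segment; the unit of fingerprinting."""

    profile_id: str
    genotypes: dict[str, SegmentGenotype]

    @property
    def segment_ids(self) -> list[str]:
        return list(self.genotypes)

    @property
    def n_het_segments(self) -> int:
        return sum(g.is_heterozygous for g in self.genotypes.values())

    def n_het_snps(self, haplotypes: Mapping[str, Mapping[int, str]]) -> int:
        """Number of heterozygous SNP sites, summed over segments.

        ``haplotypes`` maps segment_id -> {hap_id: sequence}.
        """
        total = 0
        for seg_id, g in self.genotypes.items():
            if not g.is_heterozygous:
                continue
            a, b = g.hap_pair
            sa, sb = haplotypes[seg_id][a], haplotypes[seg_id][b]
            if len(sa) != len(sb):
                raise ValueError(f"haplotype length mismatch at {seg_id}")
            total += sum(x != y for x, y in zip(sa, sb))
        return total

    def key(self, segment_ids: Optional[Sequence[str]] = None):
        """Hashable identity of the profile over the given segments."""
        segs = self.segment_ids if segment_ids is None else segment_ids
        return tuple(self.genotypes[s].hap_pair for s in segs)


@dataclass(frozen=True)
class Accession:
    accession_id: str
    name: str = ""
    origin: Optional[str] = None
    sex: str = "unknown"
    profile_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male", "unknown"):
            raise ValueError(f"sex must be female/male/unknown, got {self.sex!r}")


class FrequencyTable:
    """Per-segment haplotype relative frequencies.

    This is the input to every diversity, identity and parentage
    statistic: ``freqs[segment_id][hap_id]`` is the relative frequency
    of that haplotype among the ``n_copies[segment_id]`` gene copies
    counted (two per non-missing diploid genotype).
    """

    def __init__(
        self,
        freqs: Mapping[str, Mapping[int, float]],
        n_copies: Mapping[str, int],
    ) -> None:
        self.freqs = {s: dict(f) for s, f in freqs.items()}
        self.n_copies = dict(n_copies)
        for seg, f in self.freqs.items():
            if seg not in self.n_copies:
                raise ValueError(f"n_copies missing for segment {seg}")
            if self.n_copies[seg] < 2:
                raise ValueError(f"n_copies must be >= 2 at {seg}")
            vals = np.array(list(f.values()), dtype=float)
            if len(vals) == 0 or np.any(vals <= 0) or np.any(vals > 1):
                raise ValueError(f"frequencies at {seg} must be in (0, 1]")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {seg} sum to {vals.sum()}, not 1")

    @property
    def segment_ids(self) -> list[str]:
        return list(self.freqs)

    def __getitem__(self, segment_id: str) -> dict[int, float]:
        return self.freqs[segment_id]

    def __eq__(self, other) -> bool:
        if not isinstance(other, FrequencyTable):
            return NotImplemented
        return self.freqs == other.freqs and self.n_copies == other.n_copies


class DistanceMatrix:
    """Square symmetric dissimilarity matrix with labels."""

    def __init__(self, labels: Sequence[str], matrix) -> None:
        self.labels = list(labels)
        m = np.asarray(matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.labels):
            raise ValueError("matrix must be square and match labels")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(m, m.T, atol=1e-12, rtol=0):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be exactly zero")
        self.matrix = m

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.matrix[self.labels.index(a), self.labels.index(b)])

    def to_skbio(self):
        import skbio

        return skbio.DistanceMatrix(self.matrix, ids=self.labels)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DistanceMatrix):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(self.matrix, other.matrix)


def validate_profile(
    profile: GenotypeProfile, segments: Iterable[Segment]
) -> list[str]:
    """Check a profile against the declared segment set.

    Returns a list of human-readable violations; an empty list means
    the profile is structurally valid.  Violations are data, not
    exceptions: a validation report over a whole panel is a normal
    pipeline product.
    """
    violations: list[str] = []
    seg_ids = [s.segment_id for s in segments]
    for seg_id in seg_ids:
        if seg_id not in profile.genotypes:
            violations.append(f"segment {seg_id} absent")
    for seg_id, g in profile.genotypes.items():
        if seg_id not in seg_ids:
            violations.append(f"segment {seg_id} not declared")
        if g.segment_id != seg_id:
            violations.append(f"genotype keyed {seg_id} labelled {g.segment_id}")
        if g.hap_pair is not MISSING and g.hap_pair != canonical_pair(g.hap_pair):
            violations.append(f"pair at {seg_id} not canonical")
    return violations
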