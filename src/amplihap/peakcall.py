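"""Heterozygote base calling from chromatograph-style peak tables.

Sanger sequencing of a diploid template shows a heterozygous position
as two superimposed peaks.  A secondary peak is accepted as a real
second allele when its signal exceeds a fixed fraction of the primary
peak signal — strictly greater than 50% for single-copy amplicons and
30% for duplicated (2-copy) amplicons, where the minor allele is
diluted across four gene copies.  Accepted heterozygotes are emitted
as two-base IUPAC ambiguity codes.

Signals are taken as already-normalised linear intensities; baseline
correction and mobility normalisation belong to the upstream trace
software.  Indel-free amplicons are assumed, so no double-strand
reconciliation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

__all__ = ["PeakRecord", "PeakTrace", "call_consensus", "read_peak_table", "write_peak_table"]

#: two-base IUPAC ambiguity codes, keyed by the unordered base pair
IUPAC_2 = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("AC"): "M",
    frozenset("GT"): "K",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
}

PEAK_COLUMNS = ["position", "primary_base", "primary_signal", "secondary_base", "secondary_signal"]


@dataclass(frozen=True)
class PeakRecord:
    position: int
    primary_base: str
    primary_signal: float
    secondary_base: str
    secondary_signal: float

    def __post_init__(self) -> None:
        if self.primary_base not in "ACGTN" or self.secondary_base not in "ACGTN":
            raise ValueError(f"bases must be A/C/G/T/N at position {self.position}")
        if self.primary_signal < 0 or self.secondary_signal < 0:
            raise ValueError(f"negative signal at position {self.position}")
        if self.secondary_signal > self.primary_signal:
            raise ValueError(
                f"secondary signal exceeds primary at position {self.position}"
            )


class PeakTrace:
    """Ordered per-position primary/secondary peak calls for one read."""

    def __init__(self, records: Sequence[PeakRecord]) -> None:
        self.records = list(records)
        positions = [r.position for r in self.records]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def call_consensus(
    trace: PeakTrace,
    threshold: float,
    mask: Optional[Sequence[bool]] = None,
) -> str:
    """Diploid consensus of a peak trace as an IUPAC string.

    Per position: if ``secondary_signal / primary_signal`` is strictly
    greater than ``threshold`` and the two bases differ, the two-base
    IUPAC code is emitted; otherwise the primary base.  A primary ``N``
    or a zero primary signal yields ``N``.

    ``mask`` optionally marks positions (by index into the trace) whose
    call should be suppressed to ``N`` — the hook for discarding calls
    in poor-quality trace regions, for which no automatic rule exists.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if mask is not None and len(mask) != len(trace):
        raise ValueError("mask length must equal trace length")
    out = []
    for i, rec in enumerate(trace):
        if mask is not None and mask[i]:
            out.append("N")
            continue
        if rec.primary_base == "N" or rec.primary_signal == 0:
            out.append("N")
            continue
        ratio = rec.secondary_signal / rec.primary_signal
        if (
            ratio > threshold
            and rec.secondary_base != rec.primary_base
            and rec.secondary_base != "N"
        ):
            out.append(IUPAC_2[frozenset((rec.primary_base, rec.secondary_base))])
        else:
            out.append(rec.primary_base)
    return "".join(out)


def read_peak_table(path) -> PeakTrace:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != PEAK_COLUMNS:
        raise ValueError(f"expected columns {PEAK_COLUMNS}, got {list(df.columns)}")
    return PeakTrace(
        [
            PeakRecord(
                int(r.position),
                str(r.primary_base),
                float(r.primary_signal),
                str(r.secondary_base),
                float(r.secondary_signal),
            )
            for r in df.itertuples()
        ]
    )


def write_peak_table(trace: PeakTrace, path) -> None:
    pd.DataFrame(
        [
            (r.position, r.primary_base, r.primary_signal, r.secondary_base, r.secondary_signal)
            for r in trace
        ],
        columns=PEAK_COLUMNS,
    ).to_csv(path, sep="\t", index=False)
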