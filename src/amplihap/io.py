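"""Readers and writers for the tabular and sequence formats the pipeline touches.

All coordinates are 0-based half-open internally; 1-based only at I/O
boundaries (none of the current formats carry coordinates).
"""

from __future__ import annotations

import importlib.resources
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    MISSING,
    DistanceMatrix,
    FrequencyTable,
    GenotypeProfile,
    Segment,
    SegmentGenotype,
)

GENOTYPE_COLUMNS = ["accession_id", "segment_id", "hap_a", "hap_b"]


def read_genotype_table(path) -> tuple[list[GenotypeProfile], list[str]]:
    """Read a long-format genotype table.

    TSV with header ``accession_id  segment_id  hap_a  hap_b``; ``.``
    in both hap columns denotes a missing (failed) amplicon.  Returns
    the per-accession profiles (profile_id = accession_id; structural
    deduplication happens downstream) and the shared segment list in
    first-appearance order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != GENOTYPE_COLUMNS:
        raise ValueError(
            f"expected columns {GENOTYPE_COLUMNS}, got {list(df.columns)}"
        )
    segment_ids = list(dict.fromkeys(df["segment_id"]))
    profiles: list[GenotypeProfile] = []
    for acc, sub in df.groupby("accession_id", sort=False):
        segs = list(sub["segment_id"])
        if sorted(segs) != sorted(segment_ids):
            raise ValueError(
                f"ragged table: accession {acc} covers segments {segs}, "
                f"panel declares {segment_ids}"
            )
        genotypes = {}
        for _, row in sub.iterrows():
            a, b = row["hap_a"], row["hap_b"]
            if (a == ".") != (b == "."):
                raise ValueError(
                    f"half-missing pair for {acc} at {row['segment_id']}"
                )
            if a == ".":
                pair = MISSING
            else:
                try:
                    pair = (int(a), int(b))
                except ValueError as err:
                    raise ValueError(
                        f"non-integer hap id for {acc} at {row['segment_id']}: "
                        f"{a!r}/{b!r}"
                    ) from err
            genotypes[row["segment_id"]] = SegmentGenotype(row["segment_id"], pair)
        # preserve panel segment order in every profile
        profiles.append(
            GenotypeProfile(acc, {s: genotypes[s] for s in segment_ids})
        )
    return profiles, segment_ids


def write_genotype_table(profiles: Sequence[GenotypeProfile], path) -> None:
    rows = []
    for p in profiles:
        for seg_id, g in p.genotypes.items():
            if g.is_missing:
                a = b = "."
            else:
                a, b = g.hap_pair
            rows.append((p.profile_id, seg_id, a, b))
    pd.DataFrame(rows, columns=GENOTYPE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_frequency_table(path) -> FrequencyTable:
    df = pd.read_csv(path, sep="\t")
    freqs: dict[str, dict[int, float]] = {}
    n_copies: dict[str, int] = {}
    for seg, sub in df.groupby("segment_id", sort=False):
        freqs[seg] = dict(zip(sub["hap_id"].astype(int), sub["frequency"].astype(float)))
        n_copies[seg] = int(sub["n_copies"].iloc[0])
    return FrequencyTable(freqs, n_copies)


def write_frequency_table(table: FrequencyTable, path) -> None:
    rows = [
        (seg, hap, freq, table.n_copies[seg])
        for seg in table.segment_ids
        for hap, freq in sorted(table[seg].items())
    ]
    pd.DataFrame(rows, columns=["segment_id", "hap_id", "frequency", "n_copies"]).to_csv(
        path, sep="\t", index=False
    )


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(list(df.columns), df.to_numpy(dtype=float))


def write_distance_matrix(dm: DistanceMatrix, path, phylip: bool = False) -> None:
    if phylip:
        with open(path, "w") as fh:
            fh.write(f"{len(dm)}\n")
            for label, row in zip(dm.labels, dm.matrix):
                fh.write(label + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
    else:
        pd.DataFrame(dm.matrix, index=dm.labels, columns=dm.labels).to_csv(path, sep="\t")


def write_haplotype_fasta(haplotypes: Mapping[str, Mapping[int, str]], path) -> None:
    """Write haplotype sequences as FASTA with ids ``SEGk_HAPj``."""
    records = [
        SeqRecord(Seq(seq), id=f"{seg}_HAP{hap}", description="")
        for seg in haplotypes
        for hap, seq in sorted(haplotypes[seg].items())
    ]
    SeqIO.write(records, path, "fasta")


def read_haplotype_fasta(path) -> dict[str, dict[int, str]]:
    haplotypes: dict[str, dict[int, str]] = {}
    for rec in SeqIO.parse(path, "fasta"):
        seg, _, hap = rec.id.rpartition("_HAP")
        if not seg or not hap.isdigit():
            raise ValueError(f"haplotype record id not of form SEGk_HAPj: {rec.id!r}")
        haplotypes.setdefault(seg, {})[int(hap)] = str(rec.seq)
    return haplotypes


def read_alignment_fasta(path) -> dict[str, str]:
    """Read an aligned FASTA of same-length IUPAC consensus sequences."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")
    return seqs


def load_reference_panel() -> pd.DataFrame:
    """Summary of the published 19-segment red bayberry genotyping panel.

    One row per segment: amplicon length (bp, per copy), copy number,
    SNP and haplotype counts, haplotype diversity over all 141
    accessions and over the 72 distinct genotypes, and PIC.  Serves as
    the default panel description for the synthetic generator and for
    panel-level aggregation checks.
    """
    ref = importlib.resources.files("amplihap.data") / "segment_panel.tsv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")


def segments_from_panel(panel: Optional[pd.DataFrame] = None) -> list[Segment]:
    if panel is None:
        panel = load_reference_panel()
    return [
        Segment(
            segment_id=row.segment_id,
            amplicon_length=int(row.amplicon_length_bp),
            copy_number=int(row.copy_number),
            chrom=None if pd.isna(row.chrom) else str(row.chrom),
        )
        for row in panel.itertuples()
    ]
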