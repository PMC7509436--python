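"""Synthetic accession panels with the statistical structure the
pipeline assumes.

The generator emulates a clonally propagated fruit-crop collection
genotyped on a panel of multi-SNP amplicon segments: per-segment
haplotype frequencies are skewed (Dirichlet with small concentration,
one common haplotype plus a tail of rares), base genotypes are drawn
under Hardy–Weinberg equilibrium, clone families replicate base
genotypes (cultivar propagation and synonyms), somatic variants differ
from their progenitor at a configurable number of segments (default a
single loss-of-heterozygosity), and parent–offspring links follow
independent Mendelian segregation per segment.  Truth tables (clone
groups, somatic events, trio links) are first-class outputs so every
downstream inference can be scored against the planted structure.

Defaults mirror the red bayberry study panel: 19 segments with the
published per-segment haplotype counts (mean 7.8), 141 accessions
collapsing to 72 distinct genotypes, clone families capped at 18.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import (
    Accession,
    FrequencyTable,
    GenotypeProfile,
    Segment,
    SegmentGenotype,
)
from .io import load_reference_panel, segments_from_panel
from .peakcall import PeakRecord, PeakTrace

__all__ = ["SimConfig", "SimStudy", "sim_study", "sim_offspring", "sim_traces"]

BASES = "ACGT"


@dataclass
class SimConfig:
    """Study-scale defaults for the synthetic panel."""

    n_segments: int = 19
    n_accessions: int = 141
    n_base_genotypes: int = 72
    #: mean alleles per segment when segments are drawn rather than
    #: taken from the reference panel
    mean_alleles: float = 7.8
    #: mean SNP sites per segment when segments are drawn
    mean_snps: float = 9.3
    #: Dirichlet concentration for haplotype frequencies; 0.3 yields
    #: one common haplotype plus a tail of rares (mean MAF near 8-9%)
    dirichlet_conc: float = 0.3
    max_clone_family: int = 18
    #: number of base genotypes derived from another base by somatic mutation
    n_somatic: int = 1
    #: segments mutated per somatic event (DSN between progenitor and variant)
    somatic_segments: int = 1
    #: fraction of somatic events that are loss-of-heterozygosity
    #: (het (i,j) -> hom (i,i)); the rest substitute a novel haplotype
    loh_fraction: float = 1.0
    #: number of planted parent-offspring trios among the base genotypes
    n_trios: int = 8
    #: secondary/primary peak ratio at heterozygous trace positions
    het_ratio_single: float = 0.8
    het_ratio_dup: float = 0.4
    trace_noise_sd: float = 0.0
    #: use the published 19-segment panel metadata when n_segments <= 19
    use_reference_panel: bool = True

    def __post_init__(self) -> None:
        if min(self.n_segments, self.n_accessions, self.n_base_genotypes) < 1:
            raise ValueError("counts must be positive")
        if self.n_base_genotypes > self.n_accessions:
            raise ValueError("n_base_genotypes cannot exceed n_accessions")
        for rate in (self.loh_fraction,):
            if not (0 <= rate <= 1):
                raise ValueError("rates must be in [0, 1]")


@dataclass
class SimStudy:
    """A generated panel plus its ground truth."""

    config: SimConfig
    segments: list[Segment]
    haplotypes: dict[str, dict[int, str]]
    frequencies: FrequencyTable
    base_profiles: list[GenotypeProfile]
    accessions: list[Accession]
    profiles: list[GenotypeProfile]
    clone_groups: dict[str, list[str]]
    somatic_events: list[tuple[str, str, str, str]]  # (progenitor, variant, segment, kind)
    trio_links: list[tuple[str, str, str]]  # (parent_a, parent_b, child)

    def traces(
        self, accession_id: str, seed: int
    ) -> dict[str, PeakTrace]:
        """Per-segment peak traces for one accession's profile."""
        profile = next(
            p for p in self.profiles if p.profile_id == accession_id
        )
        rng = np.random.default_rng(seed)
        out = {}
        for seg in self.segments:
            g = profile.genotypes[seg.segment_id]
            if g.is_missing:
                continue
            a, b = g.hap_pair
            ratio = (
                self.config.het_ratio_single
                if seg.copy_number == 1
                else self.config.het_ratio_dup
            )
            out[seg.segment_id] = sim_traces(
                self.haplotypes[seg.segment_id][a],
                self.haplotypes[seg.segment_id][b],
                het_ratio=ratio,
                noise_sd=self.config.trace_noise_sd,
                seed=int(rng.integers(2**31)),
            )
        return out


def _draw_haplotypes(rng, k: int, n_sites: int) -> list[str]:
    """k distinct haplotype sequences over n_sites biallelic SNPs."""
    ref = rng.choice(list(BASES), size=n_sites)
    alt = np.array(
        [rng.choice([b for b in BASES if b != r]) for r in ref]
    )
    patterns = rng.choice(2**n_sites, size=k, replace=False)
    seqs = []
    for pat in patterns:
        bits = [(int(pat) >> s) & 1 for s in range(n_sites)]
        seqs.append("".join(alt[s] if bits[s] else ref[s] for s in range(n_sites)))
    return seqs


def _segment_plan(config: SimConfig, rng) -> list[tuple[Segment, int, int]]:
    """(segment, n_alleles, n_snps) per segment."""
    plan = []
    if config.use_reference_panel and config.n_segments <= 19:
        panel = load_reference_panel()
        segments = segments_from_panel(panel)[: config.n_segments]
        for seg, row in zip(segments, panel.itertuples()):
            k = int(row.n_haplotypes)
            n_snps = max(int(row.n_snps), math.ceil(math.log2(max(k, 2))))
            plan.append((seg, k, n_snps))
    else:
        for i in range(config.n_segments):
            k = int(np.clip(1 + rng.poisson(config.mean_alleles - 1), 2, 20))
            n_snps = int(
                np.clip(
                    1 + rng.poisson(max(config.mean_snps - 1, 0)),
                    math.ceil(math.log2(k)),
                    20,
                )
            )
            seg = Segment(
                segment_id=f"SEG{i + 1}",
                amplicon_length=int(rng.integers(430, 725)),
                copy_number=1,
            )
            plan.append((seg, k, n_snps))
    return plan


def _hwe_profile(
    profile_id: str, segments: Sequence[Segment], freq: FrequencyTable, rng
) -> GenotypeProfile:
    genotypes = {}
    for seg in segments:
        haps = list(freq[seg.segment_id])
        p = np.array([freq[seg.segment_id][h] for h in haps])
        pair = rng.choice(haps, size=2, p=p)
        genotypes[seg.segment_id] = SegmentGenotype(
            seg.segment_id, (int(pair[0]), int(pair[1]))
        )
    return GenotypeProfile(profile_id, genotypes)


def sim_offspring(
    parent_a: GenotypeProfile,
    parent_b: GenotypeProfile,
    seed: int,
    profile_id: str = "offspring",
) -> GenotypeProfile:
    """Mendelian offspring: one uniformly chosen haplotype per parent per segment."""
    rng = np.random.default_rng(seed)
    genotypes = {}
    for seg in parent_a.segment_ids:
        ga, gb = parent_a.genotypes[seg], parent_b.genotypes[seg]
        if ga.is_missing or gb.is_missing:
            raise ValueError(f"parent missing at segment {seg}")
        ha = ga.hap_pair[rng.integers(2)]
        hb = gb.hap_pair[rng.integers(2)]
        genotypes[seg] = SegmentGenotype(seg, (ha, hb))
    return GenotypeProfile(profile_id, genotypes)


def sim_traces(
    hap_a: str, hap_b: str, het_ratio: float, noise_sd: float, seed: int
) -> PeakTrace:
    """Forward-strand peak trace of a diploid with the given haplotype pair.

    Homozygous positions carry the base as primary peak (signal 1.0)
    with a negligible secondary; heterozygous positions add the second
    base as a secondary peak at ``het_ratio`` of the primary signal.
    Gaussian noise truncated at zero perturbs both signals.
    """
    if len(hap_a) != len(hap_b):
        raise ValueError("haplotype sequences must have equal length")
    if not (0 < het_ratio <= 1):
        raise ValueError("het_ratio must be in (0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    for i, (a, b) in enumerate(zip(hap_a, hap_b)):
        primary = max(0.0, 1.0 + rng.normal(0, noise_sd) if noise_sd else 1.0)
        if a == b:
            sec_base = rng.choice([x for x in BASES if x != a])
            secondary = max(0.0, rng.normal(0, noise_sd)) if noise_sd else 0.0
        else:
            sec_base = b
            secondary = max(0.0, het_ratio * primary + (rng.normal(0, noise_sd) if noise_sd else 0.0))
        secondary = min(secondary, primary)
        records.append(PeakRecord(i, a, primary, str(sec_base), secondary))
    return PeakTrace(records)


def _clone_multiplicities(config: SimConfig, rng) -> list[int]:
    """Skewed clone-family sizes summing to n_accessions.

    Preferential attachment (rich-get-richer) reproduces the observed
    pattern of many singleton genotypes plus a few large clone
    families, capped at ``max_clone_family`` members.
    """
    sizes = [1] * config.n_base_genotypes
    extra = config.n_accessions - config.n_base_genotypes
    for _ in range(extra):
        weights = np.array(
            [s if s < config.max_clone_family else 0 for s in sizes], dtype=float
        )
        if weights.sum() == 0:
            raise ValueError("cannot distribute accessions under max_clone_family")
        idx = rng.choice(len(sizes), p=weights / weights.sum())
        sizes[idx] += 1
    return sizes


def sim_study(config: Optional[SimConfig] = None, seed: int = 0) -> SimStudy:
    """Generate a full synthetic study panel, reproducible from the seed."""
    config = config or SimConfig()
    rng = np.random.default_rng(seed)
    plan = _segment_plan(config, rng)
    segments = [seg for seg, _, _ in plan]

    haplotypes: dict[str, dict[int, str]] = {}
    freqs: dict[str, dict[int, float]] = {}
    for seg, k, n_snps in plan:
        seqs = _draw_haplotypes(rng, k, n_snps)
        p = rng.dirichlet(np.full(k, config.dirichlet_conc))
        # guard against numerically zero frequencies, keep descending order
        p = np.maximum(p, 1e-6)
        p /= p.sum()
        order = np.argsort(-p)
        haplotypes[seg.segment_id] = {
            i + 1: seqs[j] for i, j in enumerate(order)
        }
        freqs[seg.segment_id] = {
            i + 1: float(p[j]) for i, j in enumerate(order)
        }
    n_copies = {seg.segment_id: 2 * config.n_accessions for seg in segments}
    freq_table = FrequencyTable(freqs, n_copies)

    n_children = min(config.n_trios, max(config.n_base_genotypes - 2, 0))
    n_somatic = min(config.n_somatic, config.n_base_genotypes - n_children - 1)
    n_founders = config.n_base_genotypes - n_children - n_somatic

    def base_id(i: int) -> str:
        return f"G{i + 1:02d}"

    # founders under HWE, all structurally distinct
    base_profiles: list[GenotypeProfile] = []
    seen: set = set()
    i = 0
    while len(base_profiles) < n_founders:
        prof = _hwe_profile(base_id(i), segments, freq_table, rng)
        key = prof.key()
        if key in seen:
            continue
        seen.add(key)
        base_profiles.append(prof)
        i += 1

    # planted trios: offspring of founder pairs
    trio_links: list[tuple[str, str, str]] = []
    while len(trio_links) < n_children:
        pa, pb = rng.choice(len(base_profiles), size=2, replace=False)
        child = sim_offspring(
            base_profiles[pa],
            base_profiles[pb],
            seed=int(rng.integers(2**31)),
            profile_id=base_id(i),
        )
        if child.key() in seen:
            continue
        seen.add(child.key())
        trio_links.append(
            (base_profiles[pa].profile_id, base_profiles[pb].profile_id, child.profile_id)
        )
        base_profiles.append(child)
        i += 1

    # somatic variants of existing bases
    somatic_events: list[tuple[str, str, str, str]] = []
    attempts = 0
    while len(somatic_events) < n_somatic and attempts < 1000:
        attempts += 1
        src = base_profiles[int(rng.integers(len(base_profiles)))]
        het_segs = [s for s in src.segment_ids if src.genotypes[s].is_heterozygous]
        if len(het_segs) < config.somatic_segments:
            continue
        chosen = list(rng.choice(het_segs, size=config.somatic_segments, replace=False))
        genotypes = dict(src.genotypes)
        kinds = []
        for seg_id in chosen:
            pair = genotypes[seg_id].hap_pair
            if rng.random() < config.loh_fraction:
                keep = int(pair[int(rng.integers(2))])
                genotypes[seg_id] = SegmentGenotype(seg_id, (keep, keep))
                kinds.append("loh")
            else:
                new_id = max(haplotypes[seg_id]) + 1
                template = haplotypes[seg_id][pair[0]]
                site = int(rng.integers(len(template)))
                new_base = rng.choice([b for b in BASES if b != template[site]])
                haplotypes[seg_id][new_id] = (
                    template[:site] + str(new_base) + template[site + 1 :]
                )
                genotypes[seg_id] = SegmentGenotype(seg_id, (int(pair[1]), new_id))
                kinds.append("new_allele")
        variant = GenotypeProfile(base_id(i), genotypes)
        if variant.key() in seen:
            continue
        seen.add(variant.key())
        base_profiles.append(variant)
        for seg_id, kind in zip(chosen, kinds):
            somatic_events.append((src.profile_id, variant.profile_id, seg_id, kind))
        i += 1
    if len(somatic_events) < n_somatic:
        raise RuntimeError("failed to place somatic variants; panel too homozygous")

    # clone families
    sizes = _clone_multiplicities(config, rng)
    accessions: list[Accession] = []
    profiles: list[GenotypeProfile] = []
    clone_groups: dict[str, list[str]] = {}
    acc_no = 0
    for base, size in zip(base_profiles, sizes):
        members = []
        for _ in range(size):
            acc_no += 1
            acc_id = f"ACC{acc_no:03d}"
            accessions.append(
                Accession(acc_id, name=acc_id, sex="female", profile_id=base.profile_id)
            )
            profiles.append(GenotypeProfile(acc_id, dict(base.genotypes)))
            members.append(acc_id)
        clone_groups[base.profile_id] = members

    return SimStudy(
        config=config,
        segments=segments,
        haplotypes=haplotypes,
        frequencies=freq_table,
        base_profiles=base_profiles,
        accessions=accessions,
        profiles=profiles,
        clone_groups=clone_groups,
        somatic_events=somatic_events,
        trio_links=trio_links,
    )
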