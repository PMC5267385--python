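"""Synthetic maize/teosinte-like multi-gene datasets.

Emulates the structure of a domestication-era resequencing panel: per gene,
~31 ingroup haplotypes split into two demes (a temperate/tropical analog),
~9 haplotypes from a sister subspecies (the wild progenitor analog) and one
distant outgroup, laid out as 5'-upstream + coding (split by one intron)
sequence with realistic lengths and per-site diversity on the order of
0.001-0.007.

Haplotypes come from the structured coalescent in :mod:`zeascan.coalescent`:
the two demes split cleanly (no migration), merge into the sister taxon's
population above the domestication-bottleneck epoch, and the outgroup joins
deepest. Infinite-sites mutations are rendered onto a random ancestral
sequence, one alignment column per mutation; mutations falling in the coding
region are steered to third codon positions with probability ``p_syn`` and
given a synonymous derived base when one exists, which yields realistic
pi_a/pi_s below one. Optional site-frequency distortions emulate sweep-like
(excess singletons) or balancing-like (excess intermediate frequencies)
signatures without forward simulation.

Every output is a deterministic function of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignments import (
    HaplotypeMatrix,
    PopulationMap,
    RegionAnnotation,
    SequenceAlignment,
    write_bed,
    write_fasta,
    write_population_map,
)
from .coalescent import DemographicModel, mutate, simulate_genealogy
from .divergence import is_stop, _BASES, _CODE

DISTORTION_MODES = ("none", "sweep_like", "balancing_like")


def default_demography() -> DemographicModel:
    """Illustrative domestication bottleneck with severity k = 2.45.

    Only the severity ratio is anchored in the motivating study
    (k = x_b / t_b = 2.45); the absolute onset/duration here are illustrative
    defaults (onset 0.01, duration 0.0204, bottleneck size 0.05, in 4*N0
    units), not a calibrated demography.
    """
    return DemographicModel.bottleneck(t_d=0.01, t_b=0.0204, x_b=0.05, x_a=1.0)


@dataclass
class SyntheticDatasetConfig:
    """Study-condition defaults for the generated panel."""

    genes: int = 3
    n_temperate: int = 14
    n_tropical: int = 17
    n_sister: int = 9
    five_prime_len: int = 240
    coding_range: tuple[int, int] = (600, 3600)
    intron_range: tuple[int, int] = (826, 3605)
    theta_per_site: float = 0.0065
    demography: DemographicModel = field(default_factory=default_demography)
    split_time: float = 0.007
    sister_join_time: float = 0.0304
    outgroup_join_time: float = 0.5
    outgroup_extra_theta_factor: float = 0.5
    p_syn: float = 0.7
    distortion: str = "none"
    distortion_strength: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distortion not in DISTORTION_MODES:
            raise ValueError(f"unknown distortion {self.distortion!r}")
        if self.n_temperate + self.n_tropical < 4:
            raise ValueError("need >= 4 ingroup haplotypes")

    @property
    def n_ingroup(self) -> int:
        return self.n_temperate + self.n_tropical


@dataclass
class GeneDataset:
    """One gene's rendered alignment plus generation truth."""

    name: str
    alignment: SequenceAlignment
    popmap: PopulationMap
    regions: RegionAnnotation
    matrix: HaplotypeMatrix
    truth: dict


def distort_sfs(
    matrix: HaplotypeMatrix,
    mode: str,
    strength: float,
    rng: np.random.Generator,
    rows: list[int] | None = None,
) -> HaplotypeMatrix:
    """Resample site frequencies toward a sweep-like or balancing-like SFS.

    A fraction ``strength`` of eligible sites is resampled: sweep_like sites
    become derived singletons (excess rare variants, Tajima's D < 0);
    balancing_like sites get derived count floor(n/2) (excess intermediate
    frequencies, D > 0). When ``rows`` is given, eligibility and resampling
    are restricted to those haplotypes: sites segregating within the subset
    have their subset carriers redrawn while other rows keep their states.
    Site count and positions are preserved; strength = 0 returns the input
    unchanged.
    """
    if mode not in ("sweep_like", "balancing_like"):
        raise ValueError(f"invalid distortion mode {mode!r}")
    if not (0 <= strength <= 1):
        raise ValueError("strength must be in [0, 1]")
    if strength == 0 or matrix.num_sites == 0:
        return matrix
    rows = list(range(matrix.n)) if rows is None else list(rows)
    if len(rows) < 3:
        raise ValueError("need >= 3 haplotypes in the distorted subset")
    derived = matrix.derived.copy()
    within = derived[:, rows].sum(axis=1)
    eligible = np.flatnonzero((within >= 1) & (within <= len(rows) - 1))
    k = int(round(strength * len(eligible)))
    if k == 0:
        return matrix
    chosen = rng.choice(eligible, size=k, replace=False)
    target = 1 if mode == "sweep_like" else len(rows) // 2
    for site in chosen:
        derived[site, rows] = 0
        carriers = rng.choice(len(rows), size=target, replace=False)
        for c in carriers:
            derived[site, rows[int(c)]] = 1
    return HaplotypeMatrix(matrix.n, matrix.positions.copy(), derived)


def _sample_layout(config: SyntheticDatasetConfig,
                   rng: np.random.Generator) -> RegionAnnotation:
    lo, hi = config.coding_range
    coding_len = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
    ilo, ihi = config.intron_range
    intron_len = int(rng.integers(ilo, ihi + 1))
    exon1 = 3 * (coding_len // 6)
    exon2 = coding_len - exon1
    fp = config.five_prime_len
    intervals = [
        (0, fp, "five_prime"),
        (fp, fp + exon1, "coding"),
        (fp + exon1, fp + exon1 + intron_len, "intron"),
        (fp + exon1 + intron_len, fp + exon1 + intron_len + exon2, "coding"),
    ]
    return RegionAnnotation(intervals)


def _ancestral_sequence(regions: RegionAnnotation, length: int,
                        rng: np.random.Generator) -> list[str]:
    """Random ancestral sequence whose coding frame is free of stop codons."""
    seq = [
        _BASES[int(b)] for b in rng.integers(0, 4, size=length)
    ]
    coding = regions.coding_columns_in_frame()
    non_stop = [c for c in _CODE if _CODE[c] != "*"]
    for i in range(0, len(coding), 3):
        codon = non_stop[int(rng.integers(0, len(non_stop)))]
        for j in range(3):
            seq[coding[i + j]] = codon[j]
    return seq


def _synonymous_bases(codon: str, pos: int) -> list[str]:
    out = []
    for b in _BASES:
        if b == codon[pos]:
            continue
        mutant = codon[:pos] + b + codon[pos + 1:]
        if not is_stop(mutant) and _CODE[mutant] == _CODE[codon]:
            out.append(b)
    return out


def _place_mutations(
    matrix: HaplotypeMatrix,
    regions: RegionAnnotation,
    ancestral: list[str],
    p_syn: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Assign one distinct alignment column and a derived base per site.

    Returns (columns ascending, derived bases, site order applied).
    """
    length = len(ancestral)
    if matrix.num_sites > length:
        raise ValueError(
            f"{matrix.num_sites} mutations exceed {length} columns; "
            "use a longer gene"
        )
    coding = regions.coding_columns_in_frame()
    codon_index = {int(c): (i // 3, i % 3) for i, c in enumerate(coding)}
    third = {int(coding[i]) for i in range(2, len(coding), 3)}
    unused = set(range(length))
    unused_third = set(third)
    columns = np.empty(matrix.num_sites, dtype=np.intp)
    derived_bases: list[str] = []
    for site in range(matrix.num_sites):
        col = int(rng.choice(sorted(unused)))
        if col in codon_index and rng.random() < p_syn and unused_third:
            col = int(rng.choice(sorted(unused_third)))
        unused.discard(col)
        unused_third.discard(col)
        base = None
        if col in codon_index:
            ci, pos = codon_index[col]
            codon = "".join(ancestral[coding[3 * ci + j]] for j in range(3))
            syn = _synonymous_bases(codon, pos)
            if pos == 2 and syn:
                base = syn[int(rng.integers(0, len(syn)))]
        if base is None:
            alts = [b for b in _BASES if b != ancestral[col]]
            base = alts[int(rng.integers(0, 3))]
        columns[site] = col
        derived_bases.append(base)
    order = np.argsort(columns)
    return columns[order], [derived_bases[i] for i in order], order


def build_popmap(config: SyntheticDatasetConfig) -> tuple[list[str], PopulationMap]:
    ids = (
        [f"tmp{i + 1:02d}" for i in range(config.n_temperate)]
        + [f"trp{i + 1:02d}" for i in range(config.n_tropical)]
        + [f"parv{i + 1:02d}" for i in range(config.n_sister)]
        + ["outgrp"]
    )
    pops = (
        ["temperate"] * config.n_temperate
        + ["tropical"] * config.n_tropical
        + ["sister"] * config.n_sister
        + ["outgroup"]
    )
    popmap = PopulationMap(dict(zip(ids, pops)), frozenset({"outgrp"}))
    return ids, popmap


def generate_gene_dataset(
    config: SyntheticDatasetConfig,
    gene_index: int,
) -> GeneDataset:
    """Generate one gene's alignment, popmap, regions and truth record."""
    if not (0 <= gene_index < config.genes):
        raise ValueError("gene_index out of range")
    seed = np.random.SeedSequence(config.seed).spawn(config.genes)[gene_index]
    rng = np.random.default_rng(seed)
    regions = _sample_layout(config, rng)
    length = regions.intervals[-1][1]
    theta = config.theta_per_site * length

    ids, popmap = build_popmap(config)
    sample_pops = [popmap.assignments[s] for s in ids]
    models = {
        "temperate": config.demography,
        "tropical": config.demography,
        "sister": DemographicModel.constant(),
        "outgroup": DemographicModel.constant(),
    }
    merges = [
        (config.split_time, "temperate", "tropical"),
        (config.sister_join_time, "tropical", "sister"),
        (config.outgroup_join_time, "sister", "outgroup"),
    ]
    gen = simulate_genealogy(sample_pops, models, merges, rng)
    matrix = mutate(gen, theta, rng)

    ingroup_rows = list(range(config.n_ingroup))
    if config.distortion != "none" and matrix.num_sites:
        matrix = distort_sfs(matrix, config.distortion,
                             config.distortion_strength, rng,
                             rows=ingroup_rows)

    # extra private outgroup mutations guarantee divergence/polarizability
    m_extra = int(rng.poisson(theta * config.outgroup_extra_theta_factor))
    if m_extra:
        extra_pos = rng.random(m_extra)
        flags = np.zeros((m_extra, matrix.n), dtype=np.int8)
        flags[:, -1] = 1
        pos = np.concatenate([matrix.positions, extra_pos])
        der = np.vstack([matrix.derived, flags])
        order = np.argsort(pos)
        pos, der = pos[order], der[order]
        uniq = np.concatenate(([True], np.diff(pos) > 0))
        matrix = HaplotypeMatrix(matrix.n, pos[uniq], der[uniq])

    ancestral = _ancestral_sequence(regions, length, rng)
    columns, derived_bases, order = _place_mutations(
        matrix, regions, ancestral, config.p_syn, rng
    )
    derived = matrix.derived[order] if matrix.num_sites else matrix.derived
    seqs = []
    for row in range(matrix.n):
        chars = list(ancestral)
        for site in range(matrix.num_sites):
            if derived[site, row]:
                chars[columns[site]] = derived_bases[site]
        seqs.append("".join(chars))
    aln = SequenceAlignment(ids, seqs)

    rendered = HaplotypeMatrix(matrix.n, columns.astype(float), derived) \
        if matrix.num_sites else matrix
    s_by_region = {k: 0 for k in ("five_prime", "coding", "intron")}
    for col in columns:
        s_by_region[regions.classify(int(col))] += 1
    truth = {
        "gene": f"gene{gene_index + 1:02d}",
        "length": length,
        "theta": theta,
        "theta_per_site": config.theta_per_site,
        "distortion": config.distortion,
        "distortion_strength": (
            config.distortion_strength if config.distortion != "none" else 0.0
        ),
        "split_time": config.split_time,
        "bottleneck_severity": config.demography.severity,
        "s_total": matrix.num_sites,
        "s_five_prime": s_by_region["five_prime"],
        "s_coding": s_by_region["coding"],
        "s_intron": s_by_region["intron"],
    }
    return GeneDataset(
        name=truth["gene"], alignment=aln, popmap=popmap, regions=regions,
        matrix=rendered, truth=truth,
    )


def generate_dataset(config: SyntheticDatasetConfig, outdir) -> pd.DataFrame:
    """Write the full panel: per-gene FASTA + BED, shared popmap, truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truths = []
    popmap = None
    for i in range(config.genes):
        ds = generate_gene_dataset(config, i)
        write_fasta(ds.alignment, outdir / f"{ds.name}.fasta")
        write_bed(ds.regions, ds.name, outdir / f"{ds.name}.bed")
        popmap = ds.popmap
        truths.append(ds.truth)
    write_population_map(popmap, outdir / "populations.tsv")
    truth_df = pd.DataFrame(truths)
    truth_df.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return truth_df
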