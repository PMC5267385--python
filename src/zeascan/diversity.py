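"""Per-region sequence-diversity estimators.

pi is the average per-site number of nucleotide differences between two
sequences in the sample (Nei & Li); theta_W is the Watterson estimator,
segregating sites scaled by the harmonic number a1 and the analyzed length.
pi_a and pi_s are the within-species analogs of dN and dS, built on the same
Nei-Gojobori codon engine as the divergence module but, by default, without
distance correction (within-species diversity is small).

All estimators apply complete deletion: columns carrying '-' or 'N' in the
analyzed sample set are excluded, and the effective length L_eff reported is
the number of surviving columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .alignments import (
    RegionAnnotation,
    SequenceAlignment,
    complete_deletion_mask,
    translate_coding,
)
from .divergence import codon_pair_counts, jukes_cantor
from .neutrality import alignment_site_counts, pairwise_diff_mean


@dataclass
class DiversitySummary:
    """One gene x region-class x sample-subset row of diversity statistics."""

    n: int
    l_eff: int
    s: int
    pi: float
    pi_se: float
    theta_w: float
    pi_a: float = math.nan
    pi_s: float = math.nan
    pi_a_over_pi_s: float = math.nan
    aa_poly_per_100: float = math.nan


def nucleotide_diversity(
    aln: SequenceAlignment,
    samples: Sequence[str] | None = None,
    columns: np.ndarray | None = None,
    variance: str = "total",
) -> tuple[float, float, int, int]:
    """(pi, pi_se, S, L_eff) over complete-deletion columns.

    ``variance='total'`` uses Tajima's total variance of pi (evolutionary +
    sampling); ``variance='sampling'`` keeps only the first, pi-linear term.
    Neither is claimed to reproduce any published SE exactly.
    """
    if columns is None:
        columns = complete_deletion_mask(aln, samples)
    n = aln.n if samples is None else len(list(samples))
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    l_eff = len(columns)
    if l_eff == 0:
        raise ValueError("no columns survive complete deletion")
    pi_hat = pairwise_diff_mean(aln, samples, columns)
    s, _ = alignment_site_counts(aln, samples, columns)
    pi = pi_hat / l_eff
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    if variance == "total":
        var = b1 * pi / l_eff + b2 * pi**2
    elif variance == "sampling":
        var = b1 * pi / l_eff
    else:
        raise ValueError(f"unknown variance mode {variance!r}")
    return pi, math.sqrt(var), s, l_eff


def watterson_theta(
    aln: SequenceAlignment,
    samples: Sequence[str] | None = None,
    columns: np.ndarray | None = None,
) -> float:
    """Watterson's theta per site: S / (a1 * L_eff)."""
    if columns is None:
        columns = complete_deletion_mask(aln, samples)
    n = aln.n if samples is None else len(list(samples))
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    if len(columns) == 0:
        raise ValueError("no columns survive complete deletion")
    s, _ = alignment_site_counts(aln, samples, columns)
    a1 = float(np.sum(1.0 / np.arange(1, n)))
    return s / (a1 * len(columns))


@dataclass
class PiAPiS:
    pi_a: float
    pi_s: float
    ratio: float  # NaN (flagged undefined) when pi_s == 0
    n_sites: float
    s_sites: float


def pi_a_pi_s(
    aln: SequenceAlignment,
    regions: RegionAnnotation,
    samples: Sequence[str] | None = None,
    correct: bool = False,
) -> PiAPiS:
    """Nonsynonymous / synonymous nucleotide diversity over the coding region.

    pi_a is the mean pairwise count of nonsynonymous differences divided by
    the mean pairwise count of nonsynonymous sites (Nei-Gojobori counting);
    pi_s analogously. When no pairwise synonymous diversity exists the ratio
    is flagged undefined (NaN). ``correct=True`` applies Jukes-Cantor to the
    per-pair proportions before averaging.
    """
    ids = list(aln.sample_ids) if samples is None else list(samples)
    if len(ids) < 2:
        raise ValueError("need >= 2 haplotypes")
    cols = regions.coding_columns_in_frame()
    seqs = {s: "".join(aln.row(s)[c] for c in cols) for s in ids}
    # complete deletion at codon resolution: drop codons with '-'/'N' anywhere
    keep: list[int] = []
    for i in range(0, len(cols), 3):
        if all(set(seqs[s][i:i + 3]) <= set("ACGT") for s in ids):
            keep.append(i)
    if not keep:
        raise ValueError("no complete codons shared by the sample")
    clean = {
        s: "".join(seqs[s][i:i + 3] for i in keep) for s in ids
    }
    sd = nd = ss = ns = 0.0
    pairs = list(combinations(ids, 2))
    for a, b in pairs:
        counts = codon_pair_counts(clean[a], clean[b])
        if correct:
            sd += jukes_cantor(counts.p_s) * counts.s_sites
            nd += jukes_cantor(counts.p_n) * counts.n_sites
        else:
            sd += counts.sd
            nd += counts.nd
        ss += counts.s_sites
        ns += counts.n_sites
    npairs = len(pairs)
    mean_ss, mean_ns = ss / npairs, ns / npairs
    pi_s = (sd / npairs) / mean_ss if mean_ss else 0.0
    pi_a = (nd / npairs) / mean_ns if mean_ns else 0.0
    ratio = pi_a / pi_s if pi_s > 0 else math.nan
    return PiAPiS(pi_a, pi_s, ratio, mean_ns, mean_ss)


def aa_polymorphism_rate(proteins: Sequence[str]) -> float:
    """Polymorphic amino-acid residues per 100 analyzed residues.

    Columns containing 'X' (masked codons) are excluded from the denominator.
    """
    if len(proteins) < 2:
        raise ValueError("need >= 2 protein sequences")
    if len({len(p) for p in proteins}) != 1:
        raise ValueError("protein sequences must be aligned")
    analyzed = poly = 0
    for col in zip(*proteins):
        if "X" in col:
            continue
        analyzed += 1
        if len(set(col)) > 1:
            poly += 1
    if analyzed == 0:
        raise ValueError("no analyzed columns (all masked)")
    return 100.0 * poly / analyzed


def diversity_summary(
    aln: SequenceAlignment,
    regions: RegionAnnotation | None = None,
    samples: Sequence[str] | None = None,
    region_class: str | None = None,
) -> DiversitySummary:
    """Assemble the full diversity row for one sample subset.

    When ``region_class`` is given only those columns are analyzed; coding
    statistics (pi_a/pi_s, amino-acid polymorphism) are filled only when the
    coding region is in play.
    """
    ids = list(aln.sample_ids) if samples is None else list(samples)
    region_cols = None
    if regions is not None and region_class is not None:
        region_cols = regions.columns_of(region_class)
    columns = complete_deletion_mask(aln, ids)
    if region_cols is not None:
        columns = np.intersect1d(columns, region_cols)
    pi, pi_se, s, l_eff = nucleotide_diversity(aln, ids, columns)
    theta = watterson_theta(aln, ids, columns)
    out = DiversitySummary(n=len(ids), l_eff=l_eff, s=s, pi=pi, pi_se=pi_se,
                           theta_w=theta)
    if regions is not None and region_class in (None, "coding"):
        try:
            pas = pi_a_pi_s(aln, regions, ids)
            out.pi_a, out.pi_s = pas.pi_a, pas.pi_s
            out.pi_a_over_pi_s = pas.ratio
            proteins = translate_coding(aln, regions, ids)
            out.aa_poly_per_100 = aa_polymorphism_rate(proteins)
        except ValueError:
            pass
    return out
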