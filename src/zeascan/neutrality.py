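"""Frequency-spectrum neutrality tests: Tajima's D, Fu & Li's D and F.

Tajima's D contrasts the mean number of pairwise differences (an estimate of
theta weighted toward intermediate-frequency variants) with the number of
segregating sites (weighted toward rare variants). Fu & Li's D and F contrast
total mutations eta with external-branch mutations eta_e — derived alleles
seen in exactly one sampled haplotype — and therefore require polarization
against an outgroup. Negative values indicate an excess of rare/derived
singletons (sweep or expansion); positive values an excess of
intermediate-frequency variants (balancing selection or a bottleneck).

Fu & Li variance constants use the corrected formulas of Simonsen, Churchill
& Aquadro (1995); the outgroup ("original") statistics are implemented, not
the starred within-sample versions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignments import HaplotypeMatrix, SequenceAlignment, complete_deletion_mask

__all__ = [
    "NeutralityConstants",
    "NeutralityResult",
    "neutrality_constants",
    "tajimas_d",
    "fu_li_d",
    "fu_li_f",
    "pairwise_diff_mean",
    "alignment_site_counts",
]


@dataclass(frozen=True)
class NeutralityConstants:
    """Sample-size-dependent constants for the three test statistics."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    c_n: float
    u_d: float
    v_d: float
    u_f: float
    v_f: float


def neutrality_constants(n: int) -> NeutralityConstants:
    """All variance constants for sample size ``n`` (requires n >= 4)."""
    if n < 4:
        raise ValueError("neutrality constants require n >= 4")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    c_n = 2.0 * (n * a1 - 2 * (n - 1)) / ((n - 1) * (n - 2))
    v_d = 1.0 + (a1**2 / (a2 + a1**2)) * (c_n - (n + 1) / (n - 1))
    u_d = a1 - 1.0 - v_d
    # Simonsen et al. (1995) corrected F constants; a_{n+1} = sum_{i<=n} 1/i
    a1n = a1 + 1.0 / n
    v_f = (c_n + b2 - 2.0 / (n - 1)) / (a1**2 + a2)
    u_f = (
        1.0
        + (n + 1) / (3.0 * (n - 1))
        - 4.0 * ((n + 1) / (n - 1) ** 2) * (a1n - 2.0 * n / (n + 1))
    ) / a1 - v_f
    return NeutralityConstants(
        n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2,
        c_n=c_n, u_d=u_d, v_d=v_d, u_f=u_f, v_f=v_f,
    )


def pairwise_diff_mean(source: HaplotypeMatrix | SequenceAlignment,
                       samples=None, columns=None) -> float:
    """Mean pairwise difference count pi_hat (a count, not per site).

    On alignments, differences at multiallelic columns are all counted; on
    binary matrices the infinite-sites formula sum d(n-d)/C(n,2) applies.
    """
    if isinstance(source, HaplotypeMatrix):
        n = source.n
        if n < 2:
            raise ValueError("need >= 2 haplotypes")
        d = source.derived_counts().astype(float)
        return float(np.sum(d * (n - d)) / (n * (n - 1) / 2.0))
    arr = _masked_array(source, samples, columns)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    total = 0
    for i in range(n - 1):
        total += int(np.sum(arr[i + 1:] != arr[i]))
    return total / (n * (n - 1) / 2.0)


def _masked_array(aln: SequenceAlignment, samples, columns) -> np.ndarray:
    if columns is None:
        columns = complete_deletion_mask(aln, samples)
    return aln.to_array(samples)[:, columns]


def alignment_site_counts(aln: SequenceAlignment, samples=None,
                          columns=None) -> tuple[int, int]:
    """(S, eta) for an alignment: segregating columns and total mutations.

    eta counts alleles-1 per column, so triallelic columns add 2; under
    infinite sites eta == S.
    """
    arr = _masked_array(aln, samples, columns)
    s = 0
    eta = 0
    for j in range(arr.shape[1]):
        k = len(np.unique(arr[:, j]))
        if k > 1:
            s += 1
            eta += k - 1
    return s, eta


def tajimas_d(source: HaplotypeMatrix | SequenceAlignment,
              samples=None, columns=None) -> float:
    """Tajima's D; NaN when there are no segregating sites.

    Operates on unpolarized data — no outgroup is needed.
    """
    if isinstance(source, HaplotypeMatrix):
        n = source.n
        s = source.num_sites
        pi_hat = pairwise_diff_mean(source) if s else 0.0
    else:
        arr = _masked_array(source, samples, columns)
        n = arr.shape[0]
        s, _ = alignment_site_counts(source, samples, columns)
        pi_hat = pairwise_diff_mean(source, samples, columns)
    if s == 0:
        return math.nan
    c = neutrality_constants(n)
    var = c.e1 * s + c.e2 * s * (s - 1)
    return (pi_hat - s / c.a1) / math.sqrt(var)


@dataclass
class FuLiD:
    d: float
    eta: int
    eta_e: int


def _eta_counts(matrix: HaplotypeMatrix) -> tuple[int, int]:
    d = matrix.derived_counts()
    return int(len(d)), int(np.sum(d == 1))


def fu_li_d(matrix: HaplotypeMatrix) -> FuLiD:
    """Fu & Li's D from a polarized matrix; NaN when eta = 0."""
    eta, eta_e = _eta_counts(matrix)
    if eta == 0:
        return FuLiD(math.nan, 0, 0)
    c = neutrality_constants(matrix.n)
    d = (eta - c.a1 * eta_e) / math.sqrt(c.u_d * eta + c.v_d * eta**2)
    return FuLiD(d, eta, eta_e)


def fu_li_f(matrix: HaplotypeMatrix, pi_hat: float | None = None) -> float:
    """Fu & Li's F from a polarized matrix; NaN when eta = 0.

    ``pi_hat`` (mean pairwise difference count) may be supplied from the
    alignment the matrix came from; by default it is computed from the
    matrix itself.
    """
    eta, eta_e = _eta_counts(matrix)
    if eta == 0:
        return math.nan
    if pi_hat is None:
        pi_hat = pairwise_diff_mean(matrix)
    c = neutrality_constants(matrix.n)
    return (pi_hat - eta_e) / math.sqrt(c.u_f * eta + c.v_f * eta**2)


@dataclass
class NeutralityResult:
    """Per-locus bundle of the three statistics and their percentiles."""

    n: int
    s: int
    eta: int
    eta_e: int
    pi_hat: float
    tajima_d: float
    fu_li_d: float
    fu_li_f: float
    percentile_sim: dict[str, float] | None = None
    percentile_empirical: float | None = None


def neutrality_result(matrix: HaplotypeMatrix,
                      aln_pi_hat: float | None = None,
                      s: int | None = None) -> NeutralityResult:
    """Compute all three statistics from one polarized matrix."""
    eta, eta_e = _eta_counts(matrix)
    pi_hat = pairwise_diff_mean(matrix) if eta else 0.0
    fl = fu_li_d(matrix)
    return NeutralityResult(
        n=matrix.n,
        s=matrix.num_sites if s is None else s,
        eta=eta,
        eta_e=eta_e,
        pi_hat=pi_hat if aln_pi_hat is None else aln_pi_hat,
        tajima_d=tajimas_d(matrix),
        fu_li_d=fl.d,
        fu_li_f=fu_li_f(matrix, aln_pi_hat),
    )
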