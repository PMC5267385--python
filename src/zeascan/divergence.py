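"""Between-taxon divergence: Nei-Gojobori dN/dS, relative-rate test, K score.

The Nei-Gojobori (1986) method counts, for each codon, the fractional number
of synonymous and nonsynonymous sites (each of the three positions
contributes the fraction of its single-base changes that are synonymous) and
apportions observed codon differences by averaging over all shortest
mutational pathways between the two codons, skipping pathways that pass
through a stop codon. Proportions of differences are Jukes-Cantor corrected,
d = -(3/4) ln(1 - 4p/3).

The relative-rate test (Tajima's 1D test) compares, for two ingroup lineages
A and B and an outgroup O, the counts of sites where only A (m_A) or only B
(m_B) carries a unique allele; under equal rates (m_A - m_B)^2 / (m_A + m_B)
is chi-square distributed with one degree of freedom.

The K scale factor compares the overall sizes of two phylogenies with
identical leaf sets and unrooted topologies: branches are matched by leaf
bipartition and K is the least-squares minimizer of
sum (l_ref - K * l_comp)^2, i.e. sum(l_ref*l_comp)/sum(l_comp^2). Values
below 1 mean the comparison tree is larger (has diverged more) than the
reference.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import dendropy
import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from scipy.stats import chi2 as chi2_dist

_BASES = "ACGT"
_CODE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODE[_stop] = "*"


class JukesCantorError(ValueError):
    """Observed proportion of differences >= 3/4; correction undefined."""


class TopologyMismatchError(ValueError):
    """Trees do not share an unrooted topology; unmatched bipartitions listed."""


def is_stop(codon: str) -> bool:
    return _CODE.get(codon) == "*"


@lru_cache(maxsize=None)
def syn_nonsyn_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon.

    Changes producing a stop codon count as nonsynonymous. The two fractions
    always sum to exactly 3.
    """
    if codon not in _CODE or is_stop(codon):
        raise ValueError(f"cannot count sites of codon {codon!r}")
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if not is_stop(mutant) and _CODE[mutant] == _CODE[codon]:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averages over all orderings of the differing positions; orderings whose
    intermediate codons are stops are excluded (if every ordering is blocked,
    all are used). The two counts sum to the Hamming distance of the codons.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        stop_hit = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if is_stop(nxt) and nxt != c2:
                stop_hit = True
            if _CODE[nxt] == _CODE[cur] and not is_stop(nxt) and not is_stop(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if stop_hit else valid).append((sd, nd))
    paths = valid if valid else blocked
    sd_mean = sum(p[0] for p in paths) / len(paths)
    nd_mean = sum(p[1] for p in paths) / len(paths)
    return sd_mean, nd_mean


@dataclass
class CodonPairCounts:
    """Accumulated Nei-Gojobori counts for one pair of coding sequences."""

    codons: int
    s_sites: float
    n_sites: float
    sd: float
    nd: float

    @property
    def p_s(self) -> float:
        return self.sd / self.s_sites if self.s_sites else 0.0

    @property
    def p_n(self) -> float:
        return self.nd / self.n_sites if self.n_sites else 0.0


def codon_pair_counts(seq_a: str, seq_b: str) -> CodonPairCounts:
    """Count NG sites/differences codon-by-codon for two in-frame sequences.

    Codons containing '-' or 'N' in either sequence, and codons that are
    stops in either sequence, are skipped. Site counts are averaged over the
    two sequences.
    """
    if len(seq_a) != len(seq_b) or len(seq_a) % 3:
        raise ValueError("sequences must be aligned, in frame")
    codons = 0
    s_sites = n_sites = sd = nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if any(ch not in _BASES for ch in ca + cb):
            continue
        if is_stop(ca) or is_stop(cb):
            continue
        sa = syn_nonsyn_sites(ca)
        sb = syn_nonsyn_sites(cb)
        s_sites += (sa[0] + sb[0]) / 2.0
        n_sites += (sa[1] + sb[1]) / 2.0
        d = pathway_differences(ca, cb)
        sd += d[0]
        nd += d[1]
        codons += 1
    if codons == 0:
        raise ValueError("no complete codons shared by the pair")
    return CodonPairCounts(codons, s_sites, n_sites, sd, nd)


def jukes_cantor(p: float) -> float:
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        raise JukesCantorError(f"p = {p:.4f} >= 3/4, correction undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class DivergenceResult:
    d_n: float
    d_s: float
    ratio: float  # NaN when d_s == 0
    n_sites: float
    s_sites: float
    p_n: float
    p_s: float
    outgroup_id: str = ""


def nei_gojobori_pair(seq_a: str, seq_b: str,
                      correct: bool = True) -> DivergenceResult:
    """dN/dS between two in-frame coding sequences (Jukes-Cantor corrected)."""
    counts = codon_pair_counts(seq_a, seq_b)
    p_n, p_s = counts.p_n, counts.p_s
    d_n = jukes_cantor(p_n) if correct else p_n
    d_s = jukes_cantor(p_s) if correct else p_s
    ratio = d_n / d_s if d_s > 0 else math.nan
    return DivergenceResult(d_n, d_s, ratio, counts.n_sites, counts.s_sites,
                            p_n, p_s)


def consensus_sequence(seqs: Sequence[str]) -> str:
    """Majority-rule consensus (ties broken by first-seen base; '-','N' lose)."""
    out = []
    for col in zip(*seqs):
        counts: dict[str, int] = {}
        for ch in col:
            if ch in _BASES:
                counts[ch] = counts.get(ch, 0) + 1
        out.append(max(counts, key=counts.get) if counts else "N")
    return "".join(out)


def nei_gojobori_dn_ds(ingroup_seqs: Sequence[str], outgroup_seq: str,
                       outgroup_id: str = "",
                       mode: str = "average") -> DivergenceResult:
    """dN/dS of an ingroup sample against one outgroup coding sequence.

    ``mode='average'`` computes each haplotype against the outgroup and
    averages d_n and d_s before forming the ratio; ``mode='consensus'``
    compares the majority-rule consensus instead.
    """
    if mode == "consensus":
        ingroup_seqs = [consensus_sequence(ingroup_seqs)]
    elif mode != "average":
        raise ValueError(f"unknown mode {mode!r}")
    results = [nei_gojobori_pair(s, outgroup_seq) for s in ingroup_seqs]
    d_n = float(np.mean([r.d_n for r in results]))
    d_s = float(np.mean([r.d_s for r in results]))
    return DivergenceResult(
        d_n=d_n,
        d_s=d_s,
        ratio=d_n / d_s if d_s > 0 else math.nan,
        n_sites=float(np.mean([r.n_sites for r in results])),
        s_sites=float(np.mean([r.s_sites for r in results])),
        p_n=float(np.mean([r.p_n for r in results])),
        p_s=float(np.mean([r.p_s for r in results])),
        outgroup_id=outgroup_id,
    )


@dataclass
class RelativeRateResult:
    m_a: int
    m_b: int
    chi2: float
    p_value: float


def relative_rate_test(seq_a: str, seq_b: str,
                       outgroup: str) -> RelativeRateResult:
    """Tajima's 1D relative-rate test on three aligned sequences.

    Columns with '-' or 'N' in any of the three sequences are excluded.
    m_A counts sites where A differs from both B and the outgroup while B
    equals the outgroup; m_B is symmetric. Returns NaN chi2/p when
    m_A + m_B = 0.
    """
    if not (len(seq_a) == len(seq_b) == len(outgroup)):
        raise ValueError("sequences must be aligned to equal length")
    m_a = m_b = 0
    for a, b, o in zip(seq_a, seq_b, outgroup):
        if any(ch not in _BASES for ch in (a, b, o)):
            continue
        if a != b and b == o:
            m_a += 1
        elif a != b and a == o:
            m_b += 1
    if m_a + m_b == 0:
        return RelativeRateResult(0, 0, math.nan, math.nan)
    chi2 = (m_a - m_b) ** 2 / (m_a + m_b)
    return RelativeRateResult(m_a, m_b, chi2, float(chi2_dist.sf(chi2, df=1)))


@dataclass
class KScoreResult:
    k: float
    branches: int


def _bipartition_lengths(tree: dendropy.Tree) -> dict[int, float]:
    """Map normalized leaf-bitmask -> branch length, summing split duplicates."""
    tree = tree.clone(depth=1)
    tree.is_rooted = False
    tree.deroot()
    tree.encode_bipartitions()
    full = tree.taxon_namespace.all_taxa_bitmask()
    lengths: dict[int, float] = {}
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node or edge.bipartition is None:
            continue
        mask = edge.bipartition.leafset_bitmask
        if mask == 0 or mask == full:
            continue
        if not (mask & 1):
            mask = full & ~mask
        lengths[mask] = lengths.get(mask, 0.0) + (edge.length or 0.0)
    return lengths


def k_score(reference_tree: str | dendropy.Tree,
            comparison_tree: str | dendropy.Tree) -> KScoreResult:
    """Least-squares branch-length scale factor between two newick trees.

    Requires identical leaf sets and identical unrooted topologies; branches
    are matched by leaf bipartition. K < 1 means the comparison tree is
    larger (faster-diverging) than the reference.
    """
    tns = dendropy.TaxonNamespace()

    def load(t):
        if isinstance(t, dendropy.Tree):
            return dendropy.Tree.get(data=t.as_string(schema="newick"),
                                     schema="newick", taxon_namespace=tns)
        return dendropy.Tree.get(data=str(t), schema="newick",
                                 taxon_namespace=tns)

    ref = load(reference_tree)
    comp = load(comparison_tree)
    ref_leaves = {lf.taxon.label for lf in ref.leaf_node_iter()}
    comp_leaves = {lf.taxon.label for lf in comp.leaf_node_iter()}
    if ref_leaves != comp_leaves:
        raise TopologyMismatchError(
            f"leaf sets differ: {sorted(ref_leaves ^ comp_leaves)}"
        )
    ref_len = _bipartition_lengths(ref)
    comp_len = _bipartition_lengths(comp)
    unmatched = set(ref_len) ^ set(comp_len)
    if unmatched:
        names = []
        taxa = list(tns)
        for mask in sorted(unmatched):
            names.append(
                "{" + ",".join(t.label for i, t in enumerate(taxa)
                               if mask >> i & 1) + "}"
            )
        raise TopologyMismatchError(f"unmatched bipartitions: {names}")
    lr = np.array([ref_len[m] for m in ref_len])
    lc = np.array([comp_len[m] for m in ref_len])
    denom = float(np.sum(lc**2))
    if denom <= 0:
        raise ValueError("comparison tree has no positive branch lengths")
    return KScoreResult(k=float(np.sum(lr * lc)) / denom, branches=len(lr))
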