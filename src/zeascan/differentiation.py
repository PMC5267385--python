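"""Population differentiation: Hudson-Slatkin-Maddison F_ST = 1 - Hw/Hb.

Hw is the unweighted mean of the two within-population mean pairwise
difference counts, taken over ordered haplotype pairs drawn with
replacement (denominator n^2, the frequency-weighted convention); Hb is the
mean pairwise difference count across all between-population pairs. The
with-replacement convention makes two populations with identical haplotype
contents score exactly 0 and two fixed-difference populations exactly 1, at
the cost of weighting within diversity down by (n-1)/n relative to the
unbiased sample-pair mean. F_ST of 1 means the two populations share no
genetic diversity; values near 0 mean no differentiation. Near-zero
differentiation can still produce slightly negative estimates, which are
reported as computed rather than clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignments import PopulationMap, SequenceAlignment, complete_deletion_mask


@dataclass
class DifferentiationResult:
    fst: float  # NaN when h_b == 0
    h_w: float
    h_b: float
    n1: int
    n2: int


def hudson_fst(
    aln: SequenceAlignment,
    popmap: PopulationMap,
    pop_a: str,
    pop_b: str,
) -> DifferentiationResult:
    """F_ST between two ingroup populations of an alignment.

    Complete-deletion columns are taken over the union of the two samples so
    within- and between-population differences are counted on the same sites.
    """
    ids_a = [s for s in popmap.samples_in(pop_a) if s in aln.sample_ids]
    ids_b = [s for s in popmap.samples_in(pop_b) if s in aln.sample_ids]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("each population needs >= 2 haplotypes")
    union = ids_a + ids_b
    columns = complete_deletion_mask(aln, union)
    arr = aln.to_array(union)[:, columns]
    na = len(ids_a)

    def within_mean(rows) -> float:
        # ordered pairs with replacement: denominator n^2, self pairs = 0
        total = 0
        for i in rows:
            for j in rows:
                if j > i:
                    total += int(np.sum(arr[i] != arr[j]))
        return 2.0 * total / len(rows) ** 2

    def between_mean(rows_i, rows_j) -> float:
        total = sum(
            int(np.sum(arr[i] != arr[j])) for i in rows_i for j in rows_j
        )
        return total / (len(rows_i) * len(rows_j))

    idx_a = list(range(na))
    idx_b = list(range(na, len(union)))
    hw_a = within_mean(idx_a)
    hw_b = within_mean(idx_b)
    h_w = 0.5 * (hw_a + hw_b)
    h_b = between_mean(idx_a, idx_b)
    fst = 1.0 - h_w / h_b if h_b > 0 else math.nan
    return DifferentiationResult(fst=fst, h_w=h_w, h_b=h_b,
                                 n1=na, n2=len(ids_b))
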