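"""Alignment I/O, masking, outgroup polarization and region slicing.

This module holds the plumbing every estimator downstream relies on: FASTA
alignments of per-gene haplotypes, a sample-to-population map, a BED-style
annotation of region classes (coding / intron / 5' upstream), and the binary
derived/ancestral haplotype matrix produced either by polarizing an alignment
against an outgroup or by the coalescent simulator.

Coordinates are 0-based, half-open (BED-compatible) and forward strand only;
reverse-strand genes must be pre-oriented. Missing data policy is *complete
deletion*: any column carrying '-' or 'N' in the analyzed sample set is
dropped before any statistic is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN-")
REGION_CLASSES = ("coding", "intron", "five_prime")
OUTGROUP_LABEL = "outgroup"


class AlignmentError(ValueError):
    """Sequences violate alignment invariants (lengths, alphabet)."""


class FormatError(ValueError):
    """A file does not parse as the expected format."""


@dataclass
class SequenceAlignment:
    """Aligned nucleotide haplotypes for one gene.

    All sequences are uppercase strings over ``{A,C,G,T,N,-}`` of identical
    length; sample ids are unique and preserve input order.
    """

    sample_ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise AlignmentError("sample_ids and sequences differ in count")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise AlignmentError("duplicate sample ids")
        if not self.sequences:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError("unequal lengths among aligned sequences")
        if next(iter(lengths)) < 1:
            raise AlignmentError("alignment length must be >= 1")
        for sid, seq in zip(self.sample_ids, self.sequences):
            bad = set(seq) - ALPHABET
            if bad:
                raise AlignmentError(
                    f"illegal character {sorted(bad)!r} in sequence {sid!r}"
                )

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def row(self, sample_id: str) -> str:
        return self.sequences[self.sample_ids.index(sample_id)]

    def subset(self, sample_ids: Iterable[str]) -> "SequenceAlignment":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.sample_ids]
        if missing:
            raise KeyError(f"samples not in alignment: {missing}")
        return SequenceAlignment(ids, [self.row(s) for s in ids])

    def to_array(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        """Return an (n, L) uint8 byte matrix for vectorized column work."""
        seqs = self.sequences if sample_ids is None else [
            self.row(s) for s in sample_ids
        ]
        return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
            len(seqs), self.length
        )


@dataclass
class PopulationMap:
    """Sample -> population assignment with a designated outgroup set."""

    assignments: dict[str, str]
    outgroup_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.outgroup_ids = frozenset(self.outgroup_ids)
        for og in self.outgroup_ids:
            if og not in self.assignments:
                raise ValueError(f"outgroup id {og!r} missing from assignments")
        if not self.ingroup_ids():
            raise ValueError("no ingroup samples")

    def ingroup_ids(self) -> list[str]:
        return [s for s in self.assignments if s not in self.outgroup_ids]

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.ingroup_ids():
            seen.setdefault(self.assignments[s], None)
        return list(seen)

    def samples_in(self, population: str) -> list[str]:
        return [
            s
            for s in self.ingroup_ids()
            if self.assignments[s] == population
        ]


@dataclass
class RegionAnnotation:
    """Non-overlapping half-open intervals labelled coding/intron/five_prime."""

    intervals: list[tuple[int, int, str]]
    coding_frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.coding_frame_offset not in (0, 1, 2):
            raise ValueError("coding_frame_offset must be 0, 1 or 2")
        ivs = sorted(self.intervals)
        for start, end, klass in ivs:
            if klass not in REGION_CLASSES:
                raise ValueError(f"unknown region class {klass!r}")
            if not (0 <= start < end):
                raise ValueError(f"bad interval ({start}, {end})")
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError("overlapping intervals")
        self.intervals = ivs

    def columns_of(self, klass: str) -> np.ndarray:
        """All alignment columns belonging to a region class, ascending."""
        cols: list[int] = []
        for start, end, k in self.intervals:
            if k == klass:
                cols.extend(range(start, end))
        return np.asarray(cols, dtype=np.intp)

    def coding_columns_in_frame(self) -> np.ndarray:
        """Concatenated coding columns after trimming the frame offset.

        The concatenated coding length must be a multiple of 3 after the
        offset is removed.
        """
        cols = self.columns_of("coding")[self.coding_frame_offset:]
        if len(cols) % 3 != 0:
            raise ValueError(
                "coding length not divisible by 3 after frame offset"
            )
        return cols

    def classify(self, column: int) -> str | None:
        for start, end, klass in self.intervals:
            if start <= column < end:
                return klass
        return None


@dataclass
class HaplotypeMatrix:
    """Binary derived/ancestral matrix over segregating sites.

    ``derived`` has shape (S, n) with 0 = ancestral; positions are strictly
    increasing and may be integer alignment columns or unit-interval floats
    (coalescent-simulator convention).
    """

    n: int
    positions: np.ndarray
    derived: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.derived = np.asarray(self.derived, dtype=np.int8)
        if self.derived.ndim != 2 or self.derived.shape[1] != self.n:
            raise ValueError("derived must have shape (S, n)")
        if len(self.positions) != self.derived.shape[0]:
            raise ValueError("positions and derived rows differ")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        counts = self.derived.sum(axis=1)
        if np.any((counts < 1) | (counts > self.n - 1)):
            raise ValueError("each site must be segregating (1..n-1 derived)")

    @property
    def num_sites(self) -> int:
        return self.derived.shape[0]

    def derived_counts(self) -> np.ndarray:
        return self.derived.sum(axis=1).astype(np.int64)

    def subset_rows(self, rows: Sequence[int]) -> "HaplotypeMatrix":
        """Restrict to a subset of haplotypes, dropping non-segregating sites."""
        sub = self.derived[:, list(rows)]
        counts = sub.sum(axis=1)
        keep = (counts >= 1) & (counts <= sub.shape[1] - 1)
        return HaplotypeMatrix(sub.shape[1], self.positions[keep], sub[keep])


@dataclass
class PolarizationDiagnostics:
    """Bookkeeping for columns that survive complete deletion.

    polarized + unpolarizable + monomorphic + multiallelic equals the number
    of analyzed columns (conservation).
    """

    analyzed_columns: int
    polarized: int
    unpolarizable: int
    monomorphic: int
    multiallelic: int


def read_fasta(path) -> SequenceAlignment:
    """Read an aligned FASTA into a :class:`SequenceAlignment`.

    Lowercase bases are uppercased; characters outside ``{A,C,G,T,N,-}`` are
    rejected. Requires at least two records of equal length.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise FormatError(f"{path}: FASTA must contain >= 2 records")
    ids = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    return SequenceAlignment(ids, seqs)


def write_fasta(aln: SequenceAlignment, path) -> None:
    """Write canonical FASTA (60-column wrapped); round-trips byte-identically."""
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.sample_ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_population_map(path) -> PopulationMap:
    """Read a two-column TSV (sample_id, population); 'outgroup' marks outgroups."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise FormatError(f"{path}: empty population map")
    required = {"sample_id", "population"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: needs columns sample_id, population")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicate sample ids {dups}")
    assignments = dict(zip(df["sample_id"], df["population"]))
    outgroups = frozenset(
        df.loc[df["population"] == OUTGROUP_LABEL, "sample_id"]
    )
    return PopulationMap(assignments, outgroups)


def write_population_map(popmap: PopulationMap, path) -> None:
    pd.DataFrame(
        {
            "sample_id": list(popmap.assignments),
            "population": list(popmap.assignments.values()),
        }
    ).to_csv(path, sep="\t", index=False)


def read_bed(path, coding_frame_offset: int = 0) -> RegionAnnotation:
    """Read a 4-column BED; the name field must be a region class."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: BED needs 4 columns")
            rows.append((int(parts[1]), int(parts[2]), parts[3]))
    if not rows:
        raise FormatError(f"{path}: empty BED")
    return RegionAnnotation(rows, coding_frame_offset=coding_frame_offset)


def write_bed(regions: RegionAnnotation, chrom: str, path) -> None:
    with open(path, "w") as fh:
        for start, end, klass in regions.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{klass}\n")


def complete_deletion_mask(
    aln: SequenceAlignment, samples: Sequence[str] | None = None
) -> np.ndarray:
    """Columns (ascending) where no selected sample carries '-' or 'N'."""
    arr = aln.to_array(samples)
    if arr.shape[0] == 0:
        raise ValueError("samples must be nonempty")
    bad = (arr == ord("-")) | (arr == ord("N"))
    return np.flatnonzero(~bad.any(axis=0))


def polarize(
    aln: SequenceAlignment,
    popmap: PopulationMap,
    outgroup_id: str | None = None,
    columns: np.ndarray | None = None,
) -> tuple[HaplotypeMatrix, PolarizationDiagnostics]:
    """Polarize ingroup segregating sites against one outgroup sequence.

    Biallelic ingroup columns where the outgroup carries one of the two
    alleles become matrix sites (outgroup allele = ancestral = 0). Columns
    where the outgroup carries a third allele are unpolarizable; ingroup
    columns with three or more alleles are excluded as multiallelic
    (infinite-sites polarization undefined). Both are reported in the
    diagnostics together with monomorphic columns.
    """
    if outgroup_id is None:
        in_aln = [o for o in popmap.outgroup_ids if o in aln.sample_ids]
        if len(in_aln) != 1:
            raise ValueError(
                "exactly one outgroup must be present or designated; "
                f"found {sorted(in_aln)}"
            )
        outgroup_id = in_aln[0]
    elif outgroup_id not in popmap.outgroup_ids:
        raise ValueError(f"{outgroup_id!r} is not an outgroup in the map")

    ingroup = [s for s in popmap.ingroup_ids() if s in aln.sample_ids]
    if len(ingroup) < 2:
        raise ValueError("need >= 2 ingroup haplotypes to polarize")
    used = ingroup + [outgroup_id]
    if columns is None:
        columns = complete_deletion_mask(aln, used)
    arr = aln.to_array(used)[:, columns]
    in_arr, out_row = arr[:-1], arr[-1]

    positions: list[int] = []
    flags: list[np.ndarray] = []
    unpolarizable = monomorphic = multiallelic = 0
    for j, col in enumerate(columns):
        alleles = np.unique(in_arr[:, j])
        if len(alleles) == 1:
            monomorphic += 1
        elif len(alleles) > 2:
            multiallelic += 1
        elif out_row[j] not in alleles:
            unpolarizable += 1
        else:
            positions.append(int(col))
            flags.append((in_arr[:, j] != out_row[j]).astype(np.int8))
    diag = PolarizationDiagnostics(
        analyzed_columns=len(columns),
        polarized=len(positions),
        unpolarizable=unpolarizable,
        monomorphic=monomorphic,
        multiallelic=multiallelic,
    )
    if positions:
        matrix = HaplotypeMatrix(
            len(ingroup), np.asarray(positions, dtype=float), np.array(flags)
        )
    else:
        matrix = HaplotypeMatrix(
            len(ingroup),
            np.empty(0, dtype=float),
            np.empty((0, len(ingroup)), dtype=np.int8),
        )
    return matrix, diag


def translate_coding(
    aln: SequenceAlignment,
    regions: RegionAnnotation,
    samples: Sequence[str] | None = None,
) -> list[str]:
    """Translate concatenated in-frame coding columns per haplotype.

    Codons containing '-' or 'N' translate to 'X'. Internal stop codons are
    retained as '*' with a warning (real alignments occasionally carry them
    in low-quality haplotypes).
    """
    from Bio.Data.CodonTable import standard_dna_table

    table = standard_dna_table.forward_table
    stops = set(standard_dna_table.stop_codons)
    cols = regions.coding_columns_in_frame()
    ids = list(aln.sample_ids) if samples is None else list(samples)
    proteins = []
    for sid in ids:
        seq = aln.row(sid)
        cds = "".join(seq[c] for c in cols)
        aas = []
        for i in range(0, len(cds), 3):
            codon = cds[i:i + 3]
            if "-" in codon or "N" in codon:
                aas.append("X")
            elif codon in stops:
                if i < len(cds) - 3:
                    warnings.warn(
                        f"internal stop codon at codon {i // 3} in {sid}",
                        stacklevel=2,
                    )
                aas.append("*")
            else:
                aas.append(table[codon])
        proteins.append("".join(aas))
    return proteins
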