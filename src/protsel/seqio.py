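"""Codon alignments and sequence utilities.

Reads and writes aligned FASTA, assembles in-frame codon alignments over
the 61 sense codons of the universal genetic code, builds consensus
sequences from per-individual reads, splits protamine-2 precursors into
cleaved and mature domains, computes pairwise amino-acid identities and
flags pseudogenised coding sequences.

Coordinates are 0-based, half-open, in codon units for alignments and
residue units for proteins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Data import CodonTable, IUPACData
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CODONS", "CODON_INDEX", "STOP_CODONS", "CodonAlignment", "DomainBoundary",
    "read_fasta", "write_fasta", "consensus_sequence", "split_prm2",
    "pairwise_identity", "integrity_check", "IntegrityReport",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
#: the 61 sense codons, lexicographic
CODONS: list[str] = sorted(
    "".join(c) for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in STOP_CODONS
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}
#: amino acid per sense codon
CODON_AA: list[str] = [_TABLE.forward_table[c] for c in CODONS]

# inverse IUPAC table: frozenset of bases -> ambiguity code
_IUPAC_INV = {
    frozenset(v): k for k, v in IUPACData.ambiguous_dna_values.items() if len(v) > 1
}


class AlignmentError(ValueError):
    """Records of unequal length, or malformed alignment."""


class FrameError(ValueError):
    """Sequence length not divisible by 3, or in-frame stop codon."""


@dataclass
class CodonAlignment:
    """An in-frame codon alignment over the 61 sense codons.

    ``sequences`` holds the raw aligned nucleotide strings (uppercase,
    possibly gapped with ``-``); ``codes`` is the integer view used by the
    likelihood machinery: 0..60 for sense codons, -1 for gap/ambiguous
    (treated as missing data downstream).
    """

    taxa: list[str]
    sequences: list[str]
    gene_label: str = ""
    codes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(set(self.taxa)):
            raise AlignmentError("taxa identifiers must be unique")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal record lengths: {sorted(lengths)}")
        (ln,) = lengths or {0}
        if ln % 3:
            raise FrameError(f"alignment length {ln} not divisible by 3")
        self.sequences = [s.upper() for s in self.sequences]
        codes = np.full((len(self.taxa), ln // 3), -1, dtype=np.int16)
        for r, seq in enumerate(self.sequences):
            for c in range(ln // 3):
                codon = seq[3 * c : 3 * c + 3]
                if codon in CODON_INDEX:
                    codes[r, c] = CODON_INDEX[codon]
                elif codon in STOP_CODONS:
                    raise FrameError(
                        f"in-frame stop codon {codon} at codon {c} in "
                        f"{self.taxa[r]!r}"
                    )
                # gaps / ambiguity -> -1 (missing)
        self.codes = codes

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return self.codes.shape[1]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CodonAlignment)
            and self.taxa == other.taxa
            and self.sequences == other.sequences
        )

    def slice_codons(self, start: int, stop: int) -> "CodonAlignment":
        """Sub-alignment of codon columns [start, stop)."""
        if not (0 <= start <= stop <= self.n_codons):
            raise IndexError(f"codon range [{start}, {stop}) outside alignment")
        return CodonAlignment(
            taxa=list(self.taxa),
            sequences=[s[3 * start : 3 * stop] for s in self.sequences],
            gene_label=self.gene_label,
        )

    def drop_taxa(self, taxa: set[str]) -> "CodonAlignment":
        keep = [i for i, t in enumerate(self.taxa) if t not in taxa]
        return CodonAlignment(
            taxa=[self.taxa[i] for i in keep],
            sequences=[self.sequences[i] for i in keep],
            gene_label=self.gene_label,
        )

    def clean_columns(self) -> "CodonAlignment":
        """Drop codon columns containing a gap or ambiguity in any taxon.

        This is the ``cleandata`` behaviour (default on in the pipeline):
        likelihood computation then sees fully resolved columns only.
        """
        keep = np.where((self.codes >= 0).all(axis=0))[0]
        seqs = [
            "".join(s[3 * c : 3 * c + 3] for c in keep) for s in self.sequences
        ]
        return CodonAlignment(list(self.taxa), seqs, self.gene_label)

    def translate(self, taxon: str) -> str:
        """Amino-acid sequence of one row; gaps/ambiguity become ``X``/``-``."""
        row = self.sequences[self.taxa.index(taxon)]
        out = []
        for c in range(len(row) // 3):
            codon = row[3 * c : 3 * c + 3]
            if codon == "---":
                out.append("-")
            elif codon in CODON_INDEX:
                out.append(CODON_AA[CODON_INDEX[codon]])
            else:
                out.append("X")
        return "".join(out)


@dataclass(frozen=True)
class DomainBoundary:
    """Cleaved vs mature precursor partition, half-open codon intervals."""

    cleaved_range: tuple[int, int]
    mature_range: tuple[int, int]

    def __post_init__(self) -> None:
        c0, c1 = self.cleaved_range
        m0, m1 = self.mature_range
        if not (0 <= c0 <= c1 == m0 <= m1):
            raise ValueError(
                "cleaved and mature ranges must be contiguous, disjoint and "
                "ordered: cleaved then mature"
            )


def read_fasta(path, gene_label: str = "") -> CodonAlignment:
    """Read an aligned, in-frame FASTA file into a :class:`CodonAlignment`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no records in {path}")
    return CodonAlignment(
        taxa=[r.id for r in records],
        sequences=[str(r.seq) for r in records],
        gene_label=gene_label,
    )


def write_fasta(alignment: CodonAlignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=t, description="")
        for t, s in zip(alignment.taxa, alignment.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def consensus_sequence(individual_seqs: list[str]) -> str:
    """Column-majority consensus of equal-length nucleotide sequences.

    Ties resolve to the IUPAC ambiguity code covering the tied bases
    (e.g. a T/C tie gives Y).  Requires at least two sequences.
    """
    if len(individual_seqs) < 2:
        raise ValueError("need at least 2 sequences for a consensus")
    seqs = [s.upper() for s in individual_seqs]
    if len({len(s) for s in seqs}) > 1:
        raise AlignmentError("consensus input sequences must be equal length")
    out = []
    for col in zip(*seqs):
        counts: dict[str, int] = {}
        for b in col:
            counts[b] = counts.get(b, 0) + 1
        top = max(counts.values())
        winners = frozenset(b for b, n in counts.items() if n == top)
        if len(winners) == 1:
            out.append(next(iter(winners)))
        else:
            out.append(_IUPAC_INV.get(winners, "N"))
    return "".join(out)


def split_prm2(
    alignment: CodonAlignment, boundary: DomainBoundary
) -> tuple[CodonAlignment, CodonAlignment]:
    """Split a protamine-2 precursor alignment into (cleaved, mature) parts.

    The boundary must cover the whole precursor; concatenating the two
    returned sub-alignments restores the input.
    """
    c0, c1 = boundary.cleaved_range
    m0, m1 = boundary.mature_range
    if m1 != alignment.n_codons or c0 != 0:
        raise IndexError(
            f"boundary {boundary} does not cover precursor of "
            f"{alignment.n_codons} codons"
        )
    return alignment.slice_codons(c0, c1), alignment.slice_codons(m0, m1)


def pairwise_identity(seq_a: str, seq_b: str, aligned: bool = True) -> float:
    """Percent identity between two amino-acid sequences.

    For pre-aligned input, columns with a gap in either sequence are
    excluded from the denominator.  Unaligned input is globally aligned
    first (BLOSUM-free unit scores; ties broken by the aligner).
    """
    a, b = seq_a.upper(), seq_b.upper()
    if not aligned:
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -0.5
        alig = aligner.align(a.replace("-", ""), b.replace("-", ""))[0]
        a, b = str(alig[0]), str(alig[1])
    elif len(a) != len(b):
        raise AlignmentError("aligned identity requires equal lengths")
    same = total = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        total += 1
        same += x == y
    if total == 0:
        raise ValueError("no comparable (gap-free) positions")
    return 100.0 * same / total


@dataclass
class IntegrityReport:
    """Outcome of a pseudogene screen on a coding sequence."""

    status: str                      # "intact" | "dysfunctional"
    criteria: list[str]              # triggered criteria
    best_identity: float | None = None


def integrity_check(
    seq: str,
    reference_orthologues: list[str] | None = None,
    identity_floor: float | None = None,
) -> IntegrityReport:
    """Screen a nucleotide CDS for pseudogenisation.

    Dysfunctional if any of: frame length not a multiple of 3, a premature
    (internal) stop codon, or best amino-acid identity against the
    orthologue panel below ``identity_floor`` percent.  The identity
    criterion is only applied when a floor is given; it then requires a
    non-empty reference panel.
    """
    seq = seq.upper().replace("-", "")
    criteria: list[str] = []
    if len(seq) % 3:
        criteria.append("frame_length")
    n_codons = len(seq) // 3
    for c in range(n_codons):
        codon = seq[3 * c : 3 * c + 3]
        if codon in STOP_CODONS and c < n_codons - 1:
            criteria.append(f"premature_stop@codon{c}")
            break
    best = None
    if identity_floor is not None:
        if not reference_orthologues:
            raise ValueError(
                "identity criterion requested but no reference orthologues given"
            )
        aa = str(Seq(seq[: 3 * n_codons]).translate(to_stop=True))
        if aa:
            best = max(
                pairwise_identity(aa, ref.upper().replace("*", ""), aligned=False)
                for ref in reference_orthologues
            )
        else:
            best = 0.0
        if best < identity_floor:
            criteria.append(f"identity_below_floor({best:.1f}%<{identity_floor}%)")
    status = "dysfunctional" if criteria else "intact"
    return IntegrityReport(status=status, criteria=criteria, best_identity=best)
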