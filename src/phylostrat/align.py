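"""Pairwise global/local alignment and ORF translation for the overprint screen.

Alignments are optimal dynamic-programming alignments with affine gap
costs, computed with Biopython's PairwiseAligner. Defaults mirror the
conventions of the classic tools for this job: nucleotide +5/-4 with gap
open -10 / extend -0.5, protein BLOSUM62 with the same gap costs. One
co-optimal alignment is reported; the aligner's traceback is deterministic,
so results are bit-reproducible.

Match/non-match decisions downstream use percent identity over aligned
columns together with an aligned-length floor, not e-values: the screen
only needs to tell same-frame homology (protein identity tracking
nucleotide identity) from frame-shifted translation (near-random protein
identity), and identity thresholds separate those regimes with a wide
margin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "global_align",
    "local_align",
    "translate",
    "read_fasta",
    "write_fasta",
]

_STANDARD_TABLE = unambiguous_dna_by_id[1]
_NT_ALPHABET = frozenset("ACGT")
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBZX*")


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution and affine gap scores for one alphabet.

    ``gap_open`` is the score of the first gap column, ``gap_extend`` of
    each further column; both are non-positive.
    """

    alphabet: str  # 'nucleotide' | 'protein'
    match: float = 5.0
    mismatch: float = -4.0
    matrix: str | None = None  # named protein matrix, e.g. 'BLOSUM62'
    gap_open: float = -10.0
    gap_extend: float = -0.5

    def __post_init__(self) -> None:
        if self.alphabet not in ("nucleotide", "protein"):
            raise ValueError("alphabet must be 'nucleotide' or 'protein'")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be non-positive")
        if self.matrix is None and self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")

    @classmethod
    def nucleotide_default(cls) -> "ScoringScheme":
        return cls(alphabet="nucleotide")

    @classmethod
    def protein_default(cls) -> "ScoringScheme":
        return cls(alphabet="protein", matrix="BLOSUM62")

    def _legal(self) -> frozenset:
        return _NT_ALPHABET if self.alphabet == "nucleotide" else _AA_ALPHABET


@dataclass(frozen=True)
class AlignmentResult:
    """One optimal alignment: score, gapped pair, identity, coordinates."""

    score: float
    aligned_a: str
    aligned_b: str
    identity: float  # percent over aligned columns (gaps count as columns)
    n_columns: int
    a_start: int = 0
    a_end: int = 0
    b_start: int = 0
    b_end: int = 0

    @property
    def is_empty(self) -> bool:
        return self.n_columns == 0


def _make_aligner(scheme: ScoringScheme, mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    if scheme.matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(scheme.matrix)
    else:
        aligner.match_score = scheme.match
        aligner.mismatch_score = scheme.mismatch
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    return aligner


def _validate(seq: str, scheme: ScoringScheme, label: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"sequence {label} must be non-empty")
    illegal = set(seq) - scheme._legal()
    if illegal:
        raise ValueError(
            f"sequence {label} contains characters outside the "
            f"{scheme.alphabet} alphabet: {sorted(illegal)}"
        )
    return seq


def _result_from(alignment) -> AlignmentResult:
    a_gapped, b_gapped = str(alignment[0]), str(alignment[1])
    n_cols = len(a_gapped)
    counts = alignment.counts()
    identity = 100.0 * counts.identities / n_cols if n_cols else 0.0
    blocks_a, blocks_b = alignment.aligned
    if len(blocks_a):
        a_start, a_end = int(blocks_a[0][0]), int(blocks_a[-1][1])
        b_start, b_end = int(blocks_b[0][0]), int(blocks_b[-1][1])
    else:
        a_start = a_end = b_start = b_end = 0
    return AlignmentResult(
        score=float(alignment.score),
        aligned_a=a_gapped,
        aligned_b=b_gapped,
        identity=identity,
        n_columns=n_cols,
        a_start=a_start,
        a_end=a_end,
        b_start=b_start,
        b_end=b_end,
    )


def global_align(a: str, b: str, scheme: ScoringScheme | None = None) -> AlignmentResult:
    """Optimal global (Needleman-Wunsch, affine gaps) alignment of a and b."""
    scheme = scheme or ScoringScheme.nucleotide_default()
    a = _validate(a, scheme, "a")
    b = _validate(b, scheme, "b")
    aligner = _make_aligner(scheme, "global")
    alignments = aligner.align(a, b)
    return _result_from(alignments[0])


def local_align(a: str, b: str, scheme: ScoringScheme | None = None) -> AlignmentResult:
    """Optimal local (Smith-Waterman, affine gaps) alignment of a and b.

    The score is never negative; when no positive-scoring segment pair
    exists, an empty alignment with score 0 is returned.
    """
    scheme = scheme or ScoringScheme.nucleotide_default()
    a = _validate(a, scheme, "a")
    b = _validate(b, scheme, "b")
    aligner = _make_aligner(scheme, "local")
    score = aligner.score(a, b)
    if score <= 0:
        return AlignmentResult(
            score=0.0, aligned_a="", aligned_b="", identity=0.0, n_columns=0
        )
    alignments = aligner.align(a, b)
    return _result_from(alignments[0])


def translate(nt: str, frame: int = 0) -> str:
    """Standard-code translation of ``nt`` from frame offset 0, 1 or 2.

    The trailing partial codon is dropped, translation stops at the first
    stop codon (which is not emitted), and any codon containing N yields X.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    nt = nt.upper()
    illegal = set(nt) - set("ACGTN")
    if illegal:
        raise ValueError(f"nucleotide sequence contains {sorted(illegal)}")
    out = []
    for i in range(frame, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if "N" in codon:
            out.append("X")
            continue
        if codon in _STANDARD_TABLE.stop_codons:
            break
        out.append(_STANDARD_TABLE.forward_table[codon])
    return "".join(out)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> {record id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records: Iterator[SeqRecord] = (
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sorted(sequences.items())
    )
    SeqIO.write(records, str(path), "fasta")
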