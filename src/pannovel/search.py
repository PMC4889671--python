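"""Translated protein-vs-genome homology search.

A query protein is searched against all six reading frames of every
contig with affine-gap Smith--Waterman local alignment (BLOSUM62 by
default), and raw scores are converted to bit scores with the
Karlin--Altschul parameters lambda and K:

    bits = (lambda * raw - ln K) / ln 2

This mirrors how TBLASTN ranks hits, without the seeded heuristics:
the search is exhaustive, which is exact and perfectly adequate at the
scale of the synthetic strain panels this package targets.  Hits from
external search tools can be ingested instead via the standard
12-column tabular format.

Gap convention: a gap of length L costs ``gap_open + L * gap_extend``
(the BLAST convention; the default 11/1 scheme charges 12 for a
length-1 gap).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .io import GenomeAssembly, revcomp

#: amino acids accepted in query proteins (X is the masked/unknown residue)
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

FRAMES = (1, 2, 3, -1, -2, -3)


def _blosum62_x_neutral():
    """BLOSUM62 with the X row/column zeroed so masked residues are neutral."""
    mat = substitution_matrices.load("BLOSUM62").copy()
    for aa in mat.alphabet:
        mat["X", aa] = 0.0
        mat[aa, "X"] = 0.0
    return mat


@dataclass
class ScoringScheme:
    """Scoring parameters for the translated search.

    Defaults are the standard gapped protein-search values: BLOSUM62,
    gap open 11, gap extend 1, lambda = 0.267 nats per raw-score unit,
    K = 0.041.
    """

    substitution_matrix: object = field(default_factory=_blosum62_x_neutral)
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    karlin_k: float = 0.041
    #: best raw score below this is reported as "no hit"
    raw_floor: float = 35.0

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.karlin_k <= 0:
            raise ValueError("lambda and K must be positive")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner(mode="local")
        aligner.substitution_matrix = self.substitution_matrix
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class AlignmentHit:
    """One translated-search hit.

    ``subject_start``/``subject_end`` are 1-based inclusive nucleotide
    coordinates on the forward strand of the contig; ``frame`` is in
    {+1,+2,+3,-1,-2,-3} with negative frames read off the reverse
    complement.
    """

    query_id: str
    genome_id: str
    contig_id: str
    subject_start: int
    subject_end: int
    frame: int
    raw_score: float
    bit_score: float


_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


def _translate_frame(dna: str, offset: int) -> str:
    sub = dna[offset:]
    sub = sub[: len(sub) - len(sub) % 3]
    return "".join(
        _CODON_TABLE.get(sub[i : i + 3], "X") for i in range(0, len(sub), 3)
    )


def six_frame_translate(dna: str) -> dict[int, str]:
    """Translate all six reading frames.

    Returns ``{frame: peptide}`` for frames +1..+3 (forward) and -1..-3
    (reverse complement).  Codons containing N translate to X; trailing
    partial codons are dropped.  An empty sequence yields six empty
    peptides.
    """
    dna = dna.upper()
    rc = revcomp(dna)
    out: dict[int, str] = {}
    for k in (1, 2, 3):
        out[k] = _translate_frame(dna, k - 1)
        out[-k] = _translate_frame(rc, k - 1)
    return out


def _check_peptide(pep: str, role: str) -> None:
    bad = set(pep) - AMINO_ACIDS - {"X"}
    if bad:
        raise ValueError(f"{role} contains non-amino-acid symbols: {sorted(bad)}")


def local_align(
    query: str,
    subject: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> tuple[float, tuple[int, int], tuple[int, int]]:
    """Best affine-gap local alignment score of query vs subject.

    Returns ``(raw_score, (qstart, qend), (sstart, send))`` with 0-based
    half-open intervals; the empty alignment scores 0 with empty
    intervals.  The query must contain only the 20 amino acids or X;
    the subject may additionally contain ``*`` (stop) which scores per
    the matrix.
    """
    _check_peptide(query, "query")
    if not query or not subject:
        return 0.0, (0, 0), (0, 0)
    aligner = scheme.aligner()
    score = aligner.score(query, subject)
    if score <= 0:
        return 0.0, (0, 0), (0, 0)
    aln = aligner.align(query, subject)[0]
    qblocks, sblocks = aln.aligned
    qiv = (int(qblocks[0][0]), int(qblocks[-1][1]))
    siv = (int(sblocks[0][0]), int(sblocks[-1][1]))
    return float(score), qiv, siv


def raw_to_bitscore(raw_score: float, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Karlin–Altschul conversion of a raw alignment score to bits."""
    return (scheme.lam * raw_score - math.log(scheme.karlin_k)) / math.log(2)


def _frame_to_forward(frame: int, pep_start: int, pep_end: int, contig_len: int) -> tuple[int, int]:
    """Map a peptide interval (0-based half-open) in a frame back to
    1-based inclusive forward-strand nucleotide coordinates."""
    k = abs(frame)
    nt0 = (k - 1) + 3 * pep_start          # 0-based start on the read strand
    nt1 = (k - 1) + 3 * pep_end            # 0-based end (exclusive)
    if frame > 0:
        return nt0 + 1, nt1
    return contig_len - nt1 + 1, contig_len - nt0


def best_genome_hit(
    query: str,
    query_id: str,
    genome: GenomeAssembly,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    raw_floor: float | None = None,
) -> AlignmentHit | None:
    """Maximum-bit-score hit of a protein over all contigs and frames.

    Returns None when the best raw score falls below the noise floor
    (``scheme.raw_floor`` unless overridden).
    """
    _check_peptide(query, "query")
    if not genome.contigs:
        raise ValueError("genome has no contigs")
    floor = scheme.raw_floor if raw_floor is None else raw_floor
    aligner = scheme.aligner()
    best: tuple[float, str, int, str] | None = None  # (score, contig, frame, peptide)
    for contig_id, seq in genome.contigs.items():
        frames = six_frame_translate(seq)
        for frame in FRAMES:
            pep = frames[frame]
            if not pep:
                continue
            score = aligner.score(query, pep)
            if best is None or score > best[0]:
                best = (float(score), contig_id, frame, pep)
    if best is None or best[0] < floor or best[0] <= 0:
        return None
    score, contig_id, frame, pep = best
    aln = aligner.align(query, pep)[0]
    sblocks = aln.aligned[1]
    siv = (int(sblocks[0][0]), int(sblocks[-1][1]))
    start, end = _frame_to_forward(frame, siv[0], siv[1], len(genome.contigs[contig_id]))
    return AlignmentHit(
        query_id=query_id,
        genome_id=genome.genome_id,
        contig_id=contig_id,
        subject_start=start,
        subject_end=end,
        frame=frame,
        raw_score=score,
        bit_score=raw_to_bitscore(score, scheme),
    )


def best_bit_scores(
    queries: dict[str, str],
    panel: list[GenomeAssembly],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    raw_floor: float | None = None,
) -> pd.DataFrame:
    """Best bit score of each query protein against each genome.

    Rows are query ids, columns genome ids.  Absent hits (below the
    noise floor) are recorded as 0 for downstream arithmetic.
    """
    data = {}
    for gen in panel:
        col = {}
        for qid, pep in queries.items():
            hit = best_genome_hit(pep, qid, gen, scheme, raw_floor)
            col[qid] = hit.bit_score if hit is not None else 0.0
        data[gen.genome_id] = col
    return pd.DataFrame(data).loc[list(queries)]


BLAST_TABULAR_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_tabular_hits(path: str | Path, genome_id: str | None = None) -> list[AlignmentHit]:
    """Parse 12-column BLAST tabular output into AlignmentHits.

    ``sstart > send`` encodes a minus-strand hit and is normalized to
    forward-strand coordinates with a negative frame.  Only the best
    hit per (query, subject) pair is retained.  Malformed rows raise a
    ValueError naming the line number.
    """
    best: dict[tuple[str, str], AlignmentHit] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(f"line {lineno}: expected 12 columns, got {len(fields)}")
            try:
                qseqid, sseqid = fields[0], fields[1]
                sstart, send = int(fields[8]), int(fields[9])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
            if sstart <= send:
                start, end, frame = sstart, send, 1
            else:
                start, end, frame = send, sstart, -1
            hit = AlignmentHit(
                query_id=qseqid,
                genome_id=genome_id or sseqid,
                contig_id=sseqid,
                subject_start=start,
                subject_end=end,
                frame=frame,
                raw_score=float("nan"),
                bit_score=bitscore,
            )
            key = (hit.query_id, hit.genome_id)
            if key not in best or hit.bit_score > best[key].bit_score:
                best[key] = hit
    return list(best.values())


def write_tabular_hits(hits: list[AlignmentHit], path: str | Path) -> None:
    """Write hits in the 12-column tabular dialect (unused stats zeroed)."""
    with open(path, "w") as fh:
        for h in hits:
            if h.frame < 0:
                sstart, send = h.subject_end, h.subject_start
            else:
                sstart, send = h.subject_start, h.subject_end
            fh.write(
                "\t".join(
                    str(x)
                    for x in [
                        h.query_id, h.contig_id, 0.0, 0, 0, 0, 0, 0,
                        sstart, send, 0.0, round(h.bit_score, 2),
                    ]
                )
                + "\n"
            )
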