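"""Validation, correction and merging of gene-annotation tracks.

Two annotator tracks for the same genome (e.g. a homology-transfer
track and a de novo prediction track) rarely agree everywhere.  This
module validates each gene model against the ORF grammar (ATG start,
terminal stop, no internal stop, length divisible by 3), repairs
defective models by extending or shortening ORF boundaries in frame
within a bounded window, and merges the two corrected tracks into one
call set: paired models (reciprocal overlap > 50%, same strand) keep
the member that validates, unpaired valid models are kept from either
track, and uncorrectable models with coding disruptions are retained
as pseudogenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .io import (
    GenomeAssembly,
    format_gff3_attributes,
    parse_gff3_attributes,
    read_gff3,
    write_gff3,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}

VALID_CODING = "valid_coding"
PSEUDOGENE = "pseudogene"
DUBIOUS = "dubious"
INVALID = "invalid"


@dataclass
class GeneModel:
    """A located coding feature: 1-based inclusive interval plus strand,
    status and provenance."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    status: str = VALID_CODING
    source: str = "trackA"
    correction_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def sequence(self, genome: GenomeAssembly) -> str:
        return genome.fetch(self.contig, self.start, self.end, self.strand)


@dataclass
class AnnotationSet:
    """All gene models of one annotator track (or the merged set)."""

    genome_id: str
    models: list[GeneModel]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [m.gene_id for m in self.models]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene ids in annotation set")
        self.models.sort(key=lambda m: (m.contig, m.start, m.end))

    def __len__(self) -> int:
        return len(self.models)

    def by_id(self) -> dict[str, GeneModel]:
        return {m.gene_id: m for m in self.models}


@dataclass
class MergeReport:
    corrected_A: int = 0
    corrected_B: int = 0
    kept: int = 0
    pseudogenes: int = 0
    uncorrectable: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def validate_orf(model: GeneModel, genome: GenomeAssembly) -> tuple[str, list[str]]:
    """ORF grammar check.  Returns (status, defects).

    Status is ``valid_coding`` iff the oriented sequence starts with
    ATG, ends with a stop codon, has length divisible by 3, and has no
    internal stop; otherwise the defect list enumerates what failed
    among {no_start, no_stop, internal_stop, frame_length}.
    """
    contig_len = len(genome.contigs[model.contig])
    if model.start < 1 or model.end > contig_len:
        raise ValueError(
            f"{model.gene_id}: interval {model.start}-{model.end} outside contig "
            f"(length {contig_len})"
        )
    seq = model.sequence(genome)
    defects: list[str] = []
    if len(seq) % 3 != 0:
        defects.append("frame_length")
    if seq[:3] != "ATG":
        defects.append("no_start")
    if len(seq) < 3 or seq[-3:] not in STOP_CODONS:
        defects.append("no_stop")
    n_full = len(seq) // 3
    internal = range(n_full - 1) if len(seq) % 3 == 0 else range(n_full)
    if any(seq[3 * i : 3 * i + 3] in STOP_CODONS for i in internal):
        defects.append("internal_stop")
    return (VALID_CODING if not defects else INVALID), defects


def _oriented_interval(model: GeneModel, contig_len: int) -> tuple[int, int]:
    """Interval in 5'->3' coordinates of the model's strand (1-based)."""
    if model.strand == "+":
        return model.start, model.end
    return contig_len - model.end + 1, contig_len - model.start + 1


def _forward_interval(s: int, e: int, contig_len: int, strand: str) -> tuple[int, int]:
    if strand == "+":
        return s, e
    return contig_len - e + 1, contig_len - s + 1


def correct_orf(
    model: GeneModel,
    genome: GenomeAssembly,
    window: int = 300,
    min_len: int = 30,
) -> GeneModel:
    """Repair a defective gene model by moving its boundaries in frame.

    Searches codon-step start positions within +/- window for an ATG,
    takes the first in-frame stop downstream of each candidate start,
    and keeps the candidate that validates with the smallest total
    boundary displacement (ties broken toward extension over
    shortening, then by coordinate).  Candidates shorter than
    ``min_len`` nucleotides are rejected, so a disruption cannot be
    "rescued" by a trivial ATG-stop stub.  Already-valid models are
    returned unchanged; if no candidate validates the model is returned
    unchanged and flagged uncorrectable.
    """
    status, defects = validate_orf(model, genome)
    if status == VALID_CODING:
        return model
    contig_seq = genome.contigs[model.contig]
    L = len(contig_seq)
    oriented = contig_seq if model.strand == "+" else genome.fetch(model.contig, 1, L, "-")
    s, e = _oriented_interval(model, L)

    candidates: list[tuple[float, int, int, int]] = []
    for ds in range(-(window // 3) * 3, window + 1, 3):
        ns = s + ds
        if ns < 1 or ns + 2 > L:
            continue
        if oriented[ns - 1 : ns + 2] != "ATG":
            continue
        # walk in frame to the first stop codon
        ne = None
        p = ns + 3
        limit = min(L - 2, e + window)
        while p <= limit:
            if oriented[p - 1 : p + 2] in STOP_CODONS:
                ne = p + 2
                break
            p += 3
        if ne is None or abs(ne - e) > window or ne - ns + 1 < min_len:
            continue
        disp = abs(ns - s) + abs(ne - e)
        extension = 0 if (ne - ns) >= (e - s) else 1
        candidates.append((disp, extension, ns, ne))
    if not candidates:
        out = replace(model, correction_log=model.correction_log + ["uncorrectable"])
        out.status = INVALID
        return out
    disp, _, ns, ne = min(candidates)
    fs, fe = _forward_interval(ns, ne, L, model.strand)
    out = replace(
        model,
        start=fs,
        end=fe,
        status=VALID_CODING,
        correction_log=model.correction_log
        + [f"corrected:dstart={ns - s},dend={ne - e}"],
    )
    return out


def _overlap(a: GeneModel, b: GeneModel) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def _reciprocal_pairs(
    track_a: AnnotationSet, track_b: AnnotationSet, min_frac: float = 0.5
) -> list[tuple[GeneModel, GeneModel]]:
    """Greedy one-to-one pairing by reciprocal overlap > min_frac, same strand."""
    scored = []
    for a in track_a.models:
        for b in track_b.models:
            if a.contig != b.contig or a.strand != b.strand:
                continue
            ov = _overlap(a, b)
            if ov / a.length > min_frac and ov / b.length > min_frac:
                scored.append((ov, a.gene_id, b.gene_id, a, b))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs = []
    for _, ida, idb, a, b in scored:
        if ida in used_a or idb in used_b:
            continue
        used_a.add(ida)
        used_b.add(idb)
        pairs.append((a, b))
    return pairs


def merge_annotation_sets(
    track_a: AnnotationSet,
    track_b: AnnotationSet,
    genome: GenomeAssembly,
    window: int = 300,
) -> tuple[AnnotationSet, MergeReport]:
    """Reconcile two annotator tracks into a single call set.

    Every model is first validated and, if defective, a boundary
    correction is attempted.  Models are then paired across tracks by
    reciprocal >50% same-strand overlap; each pair keeps the member
    that validates (track A preferred on ties).  Unpaired valid models
    from either track are kept, and uncorrectable models with coding
    disruptions are retained as pseudogenes.  Input "dubious" labels
    are carried through unchanged.
    """
    if track_a.genome_id != track_b.genome_id:
        raise ValueError(
            f"tracks annotate different genomes: {track_a.genome_id!r} vs {track_b.genome_id!r}"
        )
    report = MergeReport()

    def prepare(track: AnnotationSet, label: str) -> list[GeneModel]:
        out = []
        for m in track.models:
            if m.status == PSEUDOGENE:
                # pseudogene is an input designation, carried through like
                # "dubious"; no boundary correction is attempted
                out.append(replace(m))
                continue
            status, defects = validate_orf(m, genome)
            if status == VALID_CODING:
                fixed = replace(m)
                fixed.status = DUBIOUS if m.status == DUBIOUS else VALID_CODING
            else:
                fixed = correct_orf(m, genome, window)
                if fixed.status == VALID_CODING:
                    if label == "A":
                        report.corrected_A += 1
                    else:
                        report.corrected_B += 1
            out.append(fixed)
        return out

    models_a = prepare(track_a, "A")
    models_b = prepare(track_b, "B")
    set_a = AnnotationSet(track_a.genome_id, models_a, track_a.provenance)
    set_b = AnnotationSet(track_b.genome_id, models_b, track_b.provenance)

    merged: list[GeneModel] = []
    paired_a: set[str] = set()
    paired_b: set[str] = set()
    for a, b in _reciprocal_pairs(set_a, set_b):
        paired_a.add(a.gene_id)
        paired_b.add(b.gene_id)
        if a.status in (VALID_CODING, DUBIOUS):
            keep = a
        elif b.status in (VALID_CODING, DUBIOUS):
            keep = b
        else:
            keep = replace(a, status=PSEUDOGENE)
        merged.append(keep)
    for models, paired in ((set_a.models, paired_a), (set_b.models, paired_b)):
        for m in models:
            if m.gene_id in paired:
                continue
            if m.status in (VALID_CODING, DUBIOUS):
                merged.append(m)
            else:
                merged.append(replace(m, status=PSEUDOGENE))

    # de-duplicate ids that can collide when both tracks name the locus alike
    seen: dict[str, int] = {}
    final: list[GeneModel] = []
    for m in merged:
        if m.gene_id in seen:
            seen[m.gene_id] += 1
            m = replace(m, gene_id=f"{m.gene_id}.{seen[m.gene_id]}")
        else:
            seen[m.gene_id] = 0
        final.append(m)

    for m in final:
        if m.status == PSEUDOGENE:
            report.pseudogenes += 1
        if "uncorrectable" in m.correction_log:
            report.uncorrectable += 1
    report.kept = len(final)
    return AnnotationSet(track_a.genome_id, final, provenance="merged"), report


def summarize_counts(annotation: AnnotationSet, trna_count: int = 0) -> dict[str, int]:
    """Counts by status; statuses partition the model list.  tRNA rows
    are carried through from input GFF3 untouched (``trna_count``)."""
    counts = {VALID_CODING: 0, PSEUDOGENE: 0, DUBIOUS: 0, INVALID: 0}
    for m in annotation.models:
        counts[m.status] += 1
    counts["tRNA"] = trna_count
    return counts


def annotation_to_gff3(annotation: AnnotationSet, path: str | Path) -> None:
    rows = []
    for m in annotation.models:
        attrs = {"ID": m.gene_id, "status": m.status, "source_track": m.source}
        rows.append(
            {
                "seqid": m.contig,
                "source": annotation.provenance or "pannovel",
                "type": "gene",
                "start": m.start,
                "end": m.end,
                "score": ".",
                "strand": m.strand,
                "phase": ".",
                "attributes": format_gff3_attributes(attrs),
            }
        )
    write_gff3(path, rows)


def annotation_from_gff3(
    path: str | Path, genome_id: str, provenance: str = ""
) -> tuple[AnnotationSet, int]:
    """Read gene rows from GFF3; returns (AnnotationSet, tRNA row count)."""
    df = read_gff3(path)
    models = []
    trna = 0
    for _, row in df.iterrows():
        if row["type"] == "tRNA":
            trna += 1
            continue
        if row["type"] != "gene":
            continue
        attrs = parse_gff3_attributes(row["attributes"])
        models.append(
            GeneModel(
                gene_id=attrs.get("ID", f"{row['seqid']}:{row['start']}"),
                contig=row["seqid"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                status=attrs.get("status", VALID_CODING),
                source=attrs.get("source_track", provenance or "trackA"),
            )
        )
    return AnnotationSet(genome_id, models, provenance), trna
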