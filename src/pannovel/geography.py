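"""Gene geography: chromosome-end proximity, missing genes, nonsyntenic
homologs, novel-gene clusters, and assembly statistics.

"Subtelomeric" is operationalized as lying within a fixed span
(default 50 kbp, boundary inclusive) of either end of the assembled
chromosome — the region where yeast gene families turn over fastest.
Missing genes are reference genes whose best translated-search bit
score in the target genome falls below a floor; nonsyntenic homologs
are reciprocal best hits whose flanking genes do not match; clusters
are runs of flagged genes with bounded inter-gene gaps.  Contigs can
also be ordered and oriented along a related reference
(ultra-scaffolding) using unique k-mer anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, GeneModel, VALID_CODING
from .io import GenomeAssembly, revcomp
from .search import (
    DEFAULT_SCHEME,
    ScoringScheme,
    best_genome_hit,
    local_align,
    raw_to_bitscore,
)


@dataclass
class GeographyParams:
    subtelomere_span: int = 50_000
    cluster_max_gap: int = 20_000
    cluster_min_size: int = 2
    #: bit-score floor below which a reference gene counts as missing;
    #: defaults to the translated-search noise floor expressed in bits
    missing_bit_floor: float = raw_to_bitscore(DEFAULT_SCHEME.raw_floor)
    rbh_overlap_min: float = 0.5
    synteny_flank: int = 2

    def __post_init__(self) -> None:
        if min(self.subtelomere_span, self.cluster_max_gap, self.synteny_flank) <= 0:
            raise ValueError("spans, gaps and flanks must be positive")
        if self.cluster_min_size < 2:
            raise ValueError("cluster_min_size must be >= 2")


DEFAULT_PARAMS = GeographyParams()


@dataclass
class ClusterCall:
    contig: str
    members: list[str]
    start: int
    end: int
    subtelomeric: bool

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def n50(lengths: list[int]) -> int:
    """Largest L such that sequences of length >= L hold at least half
    the total length."""
    if not lengths or min(lengths) <= 0:
        raise ValueError("lengths must be nonempty and positive")
    total = sum(lengths)
    acc = 0
    for L in sorted(lengths, reverse=True):
        acc += L
        if 2 * acc >= total:
            return L
    raise AssertionError("unreachable")


def subtelomeric_classify(
    start: int, end: int, contig_length: int, params: GeographyParams = DEFAULT_PARAMS
) -> bool:
    """True iff the feature lies within the subtelomere span of either
    chromosome end (boundary inclusive)."""
    return min(start - 1, contig_length - end) <= params.subtelomere_span


def detect_missing_genes(
    reference_annotations: AnnotationSet,
    reference_genome: GenomeAssembly,
    target_genome: GenomeAssembly,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    params: GeographyParams = DEFAULT_PARAMS,
    hits: dict[str, float] | None = None,
) -> list[str]:
    """Reference genes whose best bit score in the target genome falls
    below ``missing_bit_floor``.

    ``hits`` may supply precomputed best bit scores (gene id -> bits);
    otherwise the internal translated search is run.
    """
    from .annotation import DUBIOUS
    from .search import six_frame_translate

    missing = []
    for model in reference_annotations.models:
        if model.status not in (VALID_CODING, DUBIOUS):
            continue
        if hits is not None:
            bits = hits.get(model.gene_id, 0.0)
        else:
            pep = six_frame_translate(model.sequence(reference_genome))[1].rstrip("*")
            hit = best_genome_hit(pep, model.gene_id, target_genome, scheme, raw_floor=0.0)
            bits = hit.bit_score if hit is not None else 0.0
        if bits < params.missing_bit_floor:
            missing.append(model.gene_id)
    return missing


def _flanks(annotation: AnnotationSet, gene_id: str, k: int) -> set[str]:
    """Ids of up to k neighboring genes on each side, same contig."""
    model = annotation.by_id()[gene_id]
    same = [m for m in annotation.models if m.contig == model.contig]
    idx = next(i for i, m in enumerate(same) if m.gene_id == gene_id)
    left = same[max(0, idx - k) : idx]
    right = same[idx + 1 : idx + 1 + k]
    return {m.gene_id for m in left + right}


def find_nonsyntenic_homologs(
    annot_a: AnnotationSet,
    proteins_a: dict[str, str],
    annot_b: AnnotationSet,
    proteins_b: dict[str, str],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    params: GeographyParams = DEFAULT_PARAMS,
) -> list[tuple[str, str]]:
    """Reciprocal-best-hit pairs whose flanking genes do not match.

    Protein-vs-protein best hits are computed with the package's local
    aligner; a pair qualifies when a and b are mutual best hits above
    the raw-score floor with query coverage >= ``rbh_overlap_min``, and
    none of the ``synteny_flank`` neighbors of a (mapped through id
    equality or the RBH map) occurs among b's neighbors.
    """
    aligner = scheme.aligner()
    ids_a, ids_b = list(proteins_a), list(proteins_b)
    scores = np.zeros((len(ids_a), len(ids_b)))
    for i, qa in enumerate(ids_a):
        for j, qb in enumerate(ids_b):
            scores[i, j] = aligner.score(proteins_a[qa], proteins_b[qb])

    best_ab = {ids_a[i]: ids_b[int(np.argmax(scores[i]))] for i in range(len(ids_a))}
    best_ba = {ids_b[j]: ids_a[int(np.argmax(scores[:, j]))] for j in range(len(ids_b))}
    rbh: list[tuple[str, str]] = []
    for a, b in best_ab.items():
        if best_ba.get(b) != a:
            continue
        raw = scores[ids_a.index(a), ids_b.index(b)]
        if raw < scheme.raw_floor:
            continue
        _, qiv, _ = local_align(proteins_a[a], proteins_b[b], scheme)
        if (qiv[1] - qiv[0]) / len(proteins_a[a]) < params.rbh_overlap_min:
            continue
        rbh.append((a, b))

    ortho = {a: b for a, b in rbh}
    out = []
    for a, b in rbh:
        fa = _flanks(annot_a, a, params.synteny_flank)
        fb = _flanks(annot_b, b, params.synteny_flank)
        mapped = {ortho.get(x, x) for x in fa}
        if not (mapped & fb):
            out.append((a, b))
    return out


def detect_gene_clusters(
    flagged_ids: set[str],
    annotation: AnnotationSet,
    contig_lengths: dict[str, int],
    params: GeographyParams = DEFAULT_PARAMS,
) -> list[ClusterCall]:
    """Maximal runs of flagged genes on one contig with inter-gene gaps
    <= cluster_max_gap and at least cluster_min_size members."""
    calls: list[ClusterCall] = []
    flagged = [m for m in annotation.models if m.gene_id in flagged_ids]
    by_contig: dict[str, list[GeneModel]] = {}
    for m in flagged:
        by_contig.setdefault(m.contig, []).append(m)
    for contig, models in by_contig.items():
        models.sort(key=lambda m: m.start)
        run: list[GeneModel] = []
        for m in models:
            if run and m.start - run[-1].end > params.cluster_max_gap:
                calls.extend(_close_run(run, contig, contig_lengths, params))
                run = []
            run.append(m)
        calls.extend(_close_run(run, contig, contig_lengths, params))
    return calls


def _close_run(run, contig, contig_lengths, params) -> list[ClusterCall]:
    if len(run) < params.cluster_min_size:
        return []
    start, end = run[0].start, run[-1].end
    mid = (start + end) // 2
    sub = subtelomeric_classify(mid, mid, contig_lengths[contig], params)
    return [
        ClusterCall(
            contig=contig,
            members=[m.gene_id for m in run],
            start=start,
            end=end,
            subtelomeric=sub,
        )
    ]


# ---------------------------------------------------------------------------
# reference-guided scaffolding ("ultra-scaffolding")

@dataclass
class ContigPlacement:
    contig: str
    chromosome: str | None
    order: int | None
    strand: str | None
    anchor_count: int
    median_position: float | None


def _kmer_index(reference: GenomeAssembly, k: int) -> dict[str, tuple[str, int]]:
    index: dict[str, tuple[str, int] | None] = {}
    for chrom, seq in reference.contigs.items():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            index[kmer] = None if kmer in index else (chrom, i)
    return {kmer: loc for kmer, loc in index.items() if loc is not None}


def reference_guided_scaffold(
    contigs: GenomeAssembly,
    reference: GenomeAssembly,
    k: int = 21,
    stride: int = 11,
    min_anchors: int = 3,
) -> list[ContigPlacement]:
    """Order and orient contigs along a related reference genome.

    Anchors are unique reference k-mers matched exactly (forward or
    reverse complement) at every ``stride`` positions of each contig.
    Each contig is assigned to the chromosome holding the majority of
    its anchors, ordered by median anchor position and oriented by
    majority anchor strand.  Contigs with fewer than ``min_anchors``
    anchors are reported unplaced, never dropped.
    """
    index = _kmer_index(reference, k)
    raw: list[tuple[str, str | None, str | None, float | None, int]] = []
    for name, seq in contigs.contigs.items():
        anchors: list[tuple[str, int, str]] = []
        for i in range(0, max(1, len(seq) - k + 1), stride):
            kmer = seq[i : i + k]
            loc = index.get(kmer)
            if loc is not None:
                anchors.append((loc[0], loc[1], "+"))
                continue
            loc = index.get(revcomp(kmer))
            if loc is not None:
                anchors.append((loc[0], loc[1], "-"))
        if len(anchors) < min_anchors:
            raw.append((name, None, None, None, len(anchors)))
            continue
        chroms = pd.Series([a[0] for a in anchors])
        chrom = chroms.value_counts().idxmax()
        on = [a for a in anchors if a[0] == chrom]
        strand = "+" if sum(1 for a in on if a[2] == "+") * 2 >= len(on) else "-"
        pos = float(median(a[1] for a in on))
        raw.append((name, chrom, strand, pos, len(on)))

    placements: list[ContigPlacement] = []
    placed = sorted(
        (r for r in raw if r[1] is not None), key=lambda r: (r[1], r[3])
    )
    order_by_chrom: dict[str, int] = {}
    orders = {}
    for name, chrom, strand, pos, count in placed:
        orders[name] = order_by_chrom.get(chrom, 0)
        order_by_chrom[chrom] = orders[name] + 1
    for name, chrom, strand, pos, count in raw:
        placements.append(
            ContigPlacement(
                contig=name,
                chromosome=chrom,
                order=orders.get(name),
                strand=strand,
                anchor_count=count,
                median_position=pos,
            )
        )
    return placements


def placements_to_frame(placements: list[ContigPlacement]) -> pd.DataFrame:
    return pd.DataFrame([p.__dict__ for p in placements])
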