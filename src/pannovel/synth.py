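"""Synthetic strain panels with planted, fully-known structure.

The generator emulates the inputs of a strain-panel comparative
analysis at desk scale: one reference-role strain carrying only core
genes, plus derived strains that additionally carry planted novel
genes (singletons and clusters, preferentially subtelomeric),
pseudogenes and dubious ORFs; two noisy annotator tracks derived from
the truth; and transcript / read-count / peptide evidence tables for a
focal strain.  Background DNA is i.i.d. uniform over {A,C,G,T} and
genes are random codon sequences between ATG and a stop — no
biological realism beyond the ORF grammar is attempted, which keeps
every planted signal analyzable.  Novel genes are generated unrelated
to core genes so their expected best cross-hit sits at the noise
floor.

Everything is driven by a single integer seed: identical seed and
config give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    DUBIOUS,
    PSEUDOGENE,
    VALID_CODING,
    AnnotationSet,
    GeneModel,
)
from .io import GenomeAssembly, revcomp, write_fasta, write_tsv
from .search import six_frame_translate

BASES = np.array(list("ACGT"))
STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS and a + b + c != "ATG"
]


@dataclass
class SyntheticConfig:
    """Panel-generation parameters (the study conditions).

    Defaults describe a desk-scale panel: six strains of two 30-kbp
    chromosomes, forty core genes shared by all strains, ten novel
    genes (two of them grouped into three-gene clusters) planted in
    derived strains with an 80% bias toward the subtelomere span, a few
    pseudogenes and dubious ORFs, 20% annotator noise, and 70% of
    genes truly expressed.
    """

    seed: int = 0
    n_strains: int = 6
    n_chromosomes: int = 3
    chromosome_length: int = 30_000
    n_core_genes: int = 40
    n_novel_genes: int = 10
    novel_subtelomeric_fraction: float = 0.8
    n_clusters: int = 2
    cluster_size: int = 3
    n_pseudogenes: int = 4
    n_dubious: int = 6
    annotator_error_rate: float = 0.2
    expression_fraction: float = 0.7
    subtelomere_span: int = 6_000
    min_gene_codons: int = 60
    max_gene_codons: int = 150

    def __post_init__(self) -> None:
        counts = [
            self.n_strains, self.n_chromosomes, self.chromosome_length,
            self.n_core_genes, self.n_novel_genes, self.n_clusters,
            self.cluster_size, self.n_pseudogenes, self.n_dubious,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("counts must be nonnegative")
        for p in (self.novel_subtelomeric_fraction, self.annotator_error_rate,
                  self.expression_fraction):
            if not (0 <= p <= 1):
                raise ValueError("proportions must lie in [0, 1]")
        if self.n_strains < 1 or self.n_chromosomes < 1:
            raise ValueError("need at least one strain and one chromosome")
        if self.chromosome_length < 2 * self.subtelomere_span:
            raise ValueError(
                "chromosome_length must be >= 2 * subtelomere_span so both "
                "subtelomeric and interior placements exist"
            )
        if self.n_clusters > 0 and self.n_novel_genes < self.n_clusters * self.cluster_size:
            raise ValueError("n_novel_genes too small for the requested clusters")

    @property
    def strain_ids(self) -> list[str]:
        return [f"strain{str(i).zfill(2)}" for i in range(self.n_strains)]

    @property
    def reference_id(self) -> str:
        return self.strain_ids[0]

    @property
    def focal_id(self) -> str:
        """The derived strain whose annotation and evidence are generated."""
        return self.strain_ids[1] if self.n_strains > 1 else self.strain_ids[0]


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated panel.

    ``genes``: one row per gene (status, location class, cluster id,
    expression flag, strand, sequence).  ``placements``: one row per
    (strain, gene) giving the true coding interval in that strain.
    """

    config: SyntheticConfig
    genes: pd.DataFrame
    placements: pd.DataFrame
    shared_peptide_pair: tuple[str, str] | None = None

    def annotation_for(self, strain_id: str, source: str = "truth") -> AnnotationSet:
        rows = self.placements[self.placements["strain"] == strain_id]
        status = self.genes.set_index("gene_id")["status"]
        models = [
            GeneModel(
                gene_id=r.gene_id,
                contig=r.contig,
                start=int(r.start),
                end=int(r.end),
                strand=r.strand,
                status=status[r.gene_id],
                source=source,
            )
            for r in rows.itertuples()
        ]
        return AnnotationSet(strain_id, models, provenance=source)

    def proteins_for(self, strain_id: str) -> dict[str, str]:
        """Translated products of the strain's valid coding genes
        (terminal stop removed)."""
        genes = self.genes.set_index("gene_id")
        rows = self.placements[self.placements["strain"] == strain_id]
        out = {}
        for r in rows.itertuples():
            if genes.loc[r.gene_id, "status"] not in (VALID_CODING, DUBIOUS):
                continue
            seq = genes.loc[r.gene_id, "sequence"]
            out[r.gene_id] = six_frame_translate(seq)[1].rstrip("*")
        return out

    def members_of(self, strain_id: str) -> set[str]:
        return set(self.placements.loc[self.placements["strain"] == strain_id, "gene_id"])


def _random_gene(rng: np.random.Generator, n_codons: int) -> str:
    body = "".join(rng.choice(_CODONS, size=n_codons - 2))
    stop = STOPS[rng.integers(0, 3)]
    return "ATG" + body + stop


def _disrupt(rng: np.random.Generator, seq: str) -> str:
    """Introduce one coding disruption: internal stop or 1-bp deletion."""
    n_codons = len(seq) // 3
    if rng.random() < 0.5:
        i = int(rng.integers(2, n_codons - 1))
        return seq[: 3 * i] + STOPS[rng.integers(0, 3)] + seq[3 * i + 3 :]
    i = int(rng.integers(6, len(seq) - 6))
    return seq[:i] + seq[i + 1 :]


def generate_strain_panel(
    config: SyntheticConfig,
) -> tuple[list[GenomeAssembly], SyntheticTruth]:
    """Generate the strain panel and its ground truth.

    The reference strain carries core genes (plus planted pseudogenes
    and dubious ORFs, which are shared panel-wide); each derived strain
    carries the shared genes plus a strain-specific subset of the
    planted novel genes, inserted at common anchor positions.
    """
    rng = np.random.default_rng(config.seed)
    chrom_ids = [f"chr{roman}" for roman in _romans(config.n_chromosomes)]

    # --- shared ("core-like") features: core + pseudogene + dubious ---
    records: list[dict] = []
    for i in range(config.n_core_genes):
        records.append({"gene_id": f"core{i:04d}", "status": VALID_CODING})
    for i in range(config.n_pseudogenes):
        records.append({"gene_id": f"pseudo{i:03d}", "status": PSEUDOGENE})
    for i in range(config.n_dubious):
        records.append({"gene_id": f"dub{i:03d}", "status": DUBIOUS})
    for rec in records:
        n_codons = int(rng.integers(config.min_gene_codons, config.max_gene_codons + 1))
        seq = _random_gene(rng, n_codons)
        if rec["status"] == PSEUDOGENE:
            seq = _disrupt(rng, seq)
        rec["sequence"] = seq
        rec["strand"] = "+" if rng.random() < 0.5 else "-"

    # a shared 10-codon block between two core genes exercises the
    # ambiguous-peptide filter downstream
    shared_pair = None
    if config.n_core_genes >= 2:
        a, b = records[0], records[1]
        block = a["sequence"][30:60]
        b["sequence"] = b["sequence"][:30] + block + b["sequence"][60:]
        shared_pair = (a["gene_id"], b["gene_id"])

    # --- lay the shared features out in the chromosome interiors ---
    # the subtelomere spans are kept feature-free so novel-gene
    # insertions there can never corrupt a shared gene
    span = config.subtelomere_span
    interior_lo = span + 500
    interior_hi = config.chromosome_length - span - 500
    order = rng.permutation(len(records))
    per_chrom = np.array_split(order, config.n_chromosomes)
    layout: dict[str, list[dict]] = {c: [] for c in chrom_ids}
    for chrom, idxs in zip(chrom_ids, per_chrom):
        pos = interior_lo + int(rng.integers(0, 300))
        for idx in idxs:
            rec = records[int(idx)]
            gap = int(rng.integers(150, 600))
            start = pos + gap
            end = start + len(rec["sequence"]) - 1
            if end > interior_hi:
                raise ValueError(
                    "config infeasible: shared genes do not fit on chromosomes"
                )
            layout[chrom].append({**rec, "start": start, "end": end})
            pos = end

    # reference chromosome sequences
    ref_contigs: dict[str, str] = {}
    for chrom in chrom_ids:
        seq = list("".join(rng.choice(BASES, size=config.chromosome_length)))
        for feat in layout[chrom]:
            oriented = feat["sequence"] if feat["strand"] == "+" else revcomp(feat["sequence"])
            seq[feat["start"] - 1 : feat["end"]] = oriented
        ref_contigs[chrom] = "".join(seq)

    # --- novel genes: cluster units first, then singletons ---
    derived = config.strain_ids[1:]
    novel_records: list[dict] = []
    units: list[list[dict]] = []
    gi = 0
    for ci in range(config.n_clusters):
        unit = []
        for _ in range(config.cluster_size):
            n_codons = int(rng.integers(config.min_gene_codons, config.max_gene_codons + 1))
            rec = {
                "gene_id": f"novel{gi:03d}",
                "status": VALID_CODING,
                "sequence": _random_gene(rng, n_codons),
                "strand": "+" if rng.random() < 0.5 else "-",
                "cluster_id": f"cluster{ci:02d}",
            }
            unit.append(rec)
            novel_records.append(rec)
            gi += 1
        units.append(unit)
    while gi < config.n_novel_genes:
        n_codons = int(rng.integers(config.min_gene_codons, config.max_gene_codons + 1))
        rec = {
            "gene_id": f"novel{gi:03d}",
            "status": VALID_CODING,
            "sequence": _random_gene(rng, n_codons),
            "strand": "+" if rng.random() < 0.5 else "-",
            "cluster_id": "",
        }
        units.append([rec])
        novel_records.append(rec)
        gi += 1

    # anchor position + membership per unit.  Subtelomeric units are
    # stacked into per-(chromosome, end) budgets so that even after all
    # insertions every member stays within the subtelomere span;
    # interior units are anchored in intergenic gaps of the layout.
    L = config.chromosome_length
    side_budget: dict[tuple[str, str], int] = {}
    side_anchor_seq: dict[tuple[str, str], int] = {}
    for chrom in chrom_ids:
        side_budget[(chrom, "L")] = span - 300
        side_budget[(chrom, "R")] = span - 300
    unit_plans = []
    for unit in units:
        block_len = sum(len(r["sequence"]) + 200 for r in unit)
        subtelomeric = bool(rng.random() < config.novel_subtelomeric_fraction)
        anchor = None
        if subtelomeric:
            sides = sorted(side_budget, key=lambda s: -side_budget[s])
            side = sides[0]
            if side_budget[side] >= block_len:
                side_budget[side] -= block_len
                seq_no = side_anchor_seq.get(side, 0)
                side_anchor_seq[side] = seq_no + 1
                chrom = side[0]
                # distinct stacked anchors inside the feature-free zone
                anchor = 100 + seq_no if side[1] == "L" else L - 100 + seq_no
            else:
                subtelomeric = False  # budget exhausted; place interior
        if anchor is None:
            chrom = chrom_ids[int(rng.integers(0, config.n_chromosomes))]
            feats = layout[chrom]
            gaps = []
            for f1, f2 in zip(feats, feats[1:]):
                if f2["start"] - f1["end"] > 20:
                    gaps.append(f1["end"] + (f2["start"] - f1["end"]) // 2)
            if not gaps:
                gaps = [interior_lo + 50]
            anchor = gaps[int(rng.integers(0, len(gaps)))]
        if derived:
            carriers = [s for s in derived if rng.random() < 0.5]
            if not carriers:
                carriers = [derived[int(rng.integers(0, len(derived)))]]
            if config.focal_id not in carriers and rng.random() < 0.5:
                carriers.append(config.focal_id)
        else:
            carriers = []
        for rec in unit:
            rec["location_class"] = "subtelomeric" if subtelomeric else "interior"
            rec["carriers"] = sorted(set(carriers))
        unit_plans.append({"unit": unit, "chrom": chrom, "anchor": anchor})

    # --- assemble per-strain genomes and placements ---
    assemblies: list[GenomeAssembly] = []
    placement_rows: list[dict] = []
    for strain in config.strain_ids:
        strain_units = [
            up for up in unit_plans if up["unit"][0]["carriers"] and strain in up["unit"][0]["carriers"]
        ]
        contigs: dict[str, str] = {}
        for chrom in chrom_ids:
            inserts = sorted(
                (up for up in strain_units if up["chrom"] == chrom),
                key=lambda up: up["anchor"],
            )
            base = ref_contigs[chrom]
            pieces: list[str] = []
            cursor = 0
            offset = 0
            for up in inserts:
                pieces.append(base[cursor : up["anchor"]])
                offset_here = up["anchor"] + offset
                block_parts: list[str] = []
                pos_in_block = 0
                for rec in up["unit"]:
                    gap = 200  # deterministic intra-cluster spacing
                    block_parts.append(
                        "".join(rng.choice(BASES, size=gap))
                    )
                    pos_in_block += gap
                    oriented = (
                        rec["sequence"] if rec["strand"] == "+" else revcomp(rec["sequence"])
                    )
                    start = offset_here + pos_in_block + 1
                    end = start + len(rec["sequence"]) - 1
                    placement_rows.append(
                        {
                            "strain": strain,
                            "gene_id": rec["gene_id"],
                            "contig": chrom,
                            "start": start,
                            "end": end,
                            "strand": rec["strand"],
                        }
                    )
                    block_parts.append(oriented)
                    pos_in_block += len(rec["sequence"])
                block = "".join(block_parts)
                pieces.append(block)
                offset += len(block)
                cursor = up["anchor"]
            pieces.append(base[cursor:])
            contigs[chrom] = "".join(pieces)
            # shared-feature placements, shifted by preceding insertions
            for feat in layout[chrom]:
                shift = 0
                for up in inserts:
                    if up["anchor"] <= feat["start"] - 1:
                        unit_block_len = sum(
                            len(r["sequence"]) + 200 for r in up["unit"]
                        )
                        shift += unit_block_len
                placement_rows.append(
                    {
                        "strain": strain,
                        "gene_id": feat["gene_id"],
                        "contig": chrom,
                        "start": feat["start"] + shift,
                        "end": feat["end"] + shift,
                        "strand": feat["strand"],
                    }
                )
        assemblies.append(GenomeAssembly(strain, contigs))

    # --- gene-level truth table ---
    gene_rows = []
    span = config.subtelomere_span
    for rec in records:
        # location class of shared features from their reference coords
        chrom = next(c for c in chrom_ids if any(f["gene_id"] == rec["gene_id"] for f in layout[c]))
        feat = next(f for f in layout[chrom] if f["gene_id"] == rec["gene_id"])
        near_end = min(feat["start"] - 1, config.chromosome_length - feat["end"])
        gene_rows.append(
            {
                "gene_id": rec["gene_id"],
                "status": rec["status"],
                "location_class": "subtelomeric" if near_end <= span else "interior",
                "cluster_id": "",
                "carriers": ";".join(config.strain_ids),
                "strand": rec["strand"],
                "sequence": rec["sequence"],
            }
        )
    for rec in novel_records:
        gene_rows.append(
            {
                "gene_id": rec["gene_id"],
                "status": rec["status"],
                "location_class": rec["location_class"],
                "cluster_id": rec["cluster_id"],
                "carriers": ";".join(rec["carriers"]),
                "strand": rec["strand"],
                "sequence": rec["sequence"],
            }
        )
    genes = pd.DataFrame(gene_rows)

    # expression truth: valid coding genes of the focal strain
    focal = config.focal_id
    placements = pd.DataFrame(
        placement_rows, columns=["strain", "gene_id", "contig", "start", "end", "strand"]
    ).sort_values(["strain", "contig", "start"], kind="stable").reset_index(drop=True)
    focal_members = set(placements.loc[placements["strain"] == focal, "gene_id"])
    expressed = []
    for row in genes.itertuples():
        if row.status == VALID_CODING and row.gene_id in focal_members:
            expressed.append(bool(rng.random() < config.expression_fraction))
        else:
            expressed.append(False)
    genes["expressed"] = expressed
    if shared_pair is not None and config.expression_fraction > 0:
        genes.loc[genes["gene_id"].isin(shared_pair), "expressed"] = True

    truth = SyntheticTruth(
        config=config,
        genes=genes,
        placements=placements,
        shared_peptide_pair=shared_pair,
    )
    return assemblies, truth


def _romans(n: int) -> list[str]:
    numerals = [
        "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
        "XI", "XII", "XIII", "XIV", "XV", "XVI",
    ]
    if n <= len(numerals):
        return numerals[:n]
    return numerals + [str(i + 1) for i in range(len(numerals), n)]


# ---------------------------------------------------------------------------
# annotator tracks

PERTURBATION_KINDS = ("shift_start", "shift_stop", "truncate", "drop")


def generate_annotator_calls(
    truth: SyntheticTruth,
    error_rate: float,
    seed: int,
    strain_id: str | None = None,
    kinds: tuple[str, ...] = PERTURBATION_KINDS,
) -> tuple[AnnotationSet, AnnotationSet, pd.DataFrame]:
    """Two independently-perturbed annotator tracks for one strain.

    Each track perturbs each true gene model with probability
    ``error_rate`` (codon-granular start/stop shifts, truncation, or
    dropping the model).  The returned log records every perturbation
    so downstream correction recall is measurable.
    """
    if not (0 <= error_rate <= 1):
        raise ValueError("error_rate must be in [0, 1]")
    strain_id = strain_id or truth.config.focal_id
    base = truth.annotation_for(strain_id)
    rng = np.random.default_rng(seed)
    log_rows: list[dict] = []
    tracks = []
    for label in ("trackA", "trackB"):
        models: list[GeneModel] = []
        for m in base.models:
            if rng.random() >= error_rate:
                models.append(replace(m, source=label, correction_log=[]))
                continue
            kind = kinds[int(rng.integers(0, len(kinds)))]
            log_rows.append({"track": label, "gene_id": m.gene_id, "kind": kind})
            if kind == "drop":
                continue
            codons = 3 * int(rng.integers(1, 3))  # 3 or 6 bp, whole codons
            sign = 1 if rng.random() < 0.5 else -1
            d5, d3 = 0, 0
            if kind == "shift_start":
                d5 = sign * codons
            elif kind == "shift_stop":
                d3 = sign * codons
            else:  # truncate: pull the 3' end in
                d3 = -3 * int(rng.integers(2, 6))
            if m.strand == "+":
                start, end = m.start + d5, m.end + d3
            else:
                start, end = m.start - d3, m.end - d5
            if start < 1 or end <= start:
                continue
            models.append(
                replace(m, start=start, end=end, source=label, correction_log=[])
            )
        tracks.append(AnnotationSet(strain_id, models, provenance=label))
    log = pd.DataFrame(log_rows, columns=["track", "gene_id", "kind"])
    return tracks[0], tracks[1], log


# ---------------------------------------------------------------------------
# expression / peptide evidence

CONDITIONS = ("phase1", "phase2", "phase3", "phase4")


def generate_expression_evidence(
    truth: SyntheticTruth,
    config: SyntheticConfig | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Transcript alignments, per-condition counts, and peptide
    identifications for the focal strain.

    Truly-expressed genes receive a uniquely-mapped transcript covering
    >= 60% of the gene, read counts yielding FPKM > 1 in at least one
    condition, and one unique peptide with q < 0.01.  Non-expressed
    genes receive none of the three.  If the panel carries a shared
    peptide block, one ambiguous peptide (matching both proteins) is
    emitted to exercise the uniqueness filter.
    """
    config = config or truth.config
    rng = np.random.default_rng((seed if seed is not None else config.seed) + 104729)
    focal = config.focal_id
    proteome = truth.proteins_for(focal)
    genes = truth.genes.set_index("gene_id")
    members = sorted(truth.members_of(focal))

    transcript_rows, count_rows, peptide_rows = [], [], []
    t_idx = 0
    for gid in members:
        status = genes.loc[gid, "status"]
        expressed = bool(genes.loc[gid, "expressed"])
        length = len(genes.loc[gid, "sequence"])
        # counts: all annotated genes get a row per condition
        for cond in CONDITIONS:
            if expressed:
                lam = 150 if cond == CONDITIONS[0] else 40
                count = int(rng.poisson(lam)) + 20
            else:
                count = 0
            count_rows.append(
                {"gene_id": gid, "condition": cond, "count": count, "gene_length": length}
            )
        if not expressed:
            continue
        transcript_rows.append(
            {
                "gene_id": gid,
                "transcript_id": f"trans{t_idx:04d}",
                "covered_fraction": round(float(rng.uniform(0.70, 1.0)), 3),
                "n_loci": 1,
            }
        )
        t_idx += 1
        prot = proteome.get(gid)
        if prot is None:
            continue
        pep = _unique_peptide(rng, gid, prot, proteome)
        if pep is not None:
            peptide_rows.append(
                {
                    "peptide": pep,
                    "protein_ids": gid,
                    "q_value": round(float(rng.uniform(0.0005, 0.009)), 5),
                }
            )

    if truth.shared_peptide_pair is not None:
        a, b = truth.shared_peptide_pair
        if a in proteome and b in proteome:
            shared = proteome[a][10:20]
            if shared in proteome[a] and shared in proteome[b]:
                peptide_rows.append(
                    {"peptide": shared, "protein_ids": f"{a};{b}", "q_value": 0.002}
                )

    transcripts = pd.DataFrame(
        transcript_rows, columns=["gene_id", "transcript_id", "covered_fraction", "n_loci"]
    )
    counts = pd.DataFrame(count_rows, columns=["gene_id", "condition", "count", "gene_length"])
    peptides = pd.DataFrame(peptide_rows, columns=["peptide", "protein_ids", "q_value"])
    return transcripts, counts, peptides


def _unique_peptide(
    rng: np.random.Generator, gid: str, prot: str, proteome: dict[str, str], k: int = 10
) -> str | None:
    """A k-mer of prot occurring in no other protein (up to 20 tries)."""
    if len(prot) < k:
        return None
    for _ in range(20):
        i = int(rng.integers(0, len(prot) - k + 1))
        pep = prot[i : i + k]
        owners = [pid for pid, p in proteome.items() if pep in p]
        if owners == [gid]:
            return pep
    return None


# ---------------------------------------------------------------------------
# panel export / utilities

def excise_genes(
    assembly: GenomeAssembly, truth: SyntheticTruth, gene_ids: set[str]
) -> GenomeAssembly:
    """Copy of the assembly with the given genes' coding intervals cut
    out (for building deletion targets in missing-gene analyses)."""
    rows = truth.placements[
        (truth.placements["strain"] == assembly.genome_id)
        & (truth.placements["gene_id"].isin(gene_ids))
    ]
    contigs = dict(assembly.contigs)
    for contig, group in rows.groupby("contig"):
        seq = contigs[contig]
        for r in group.sort_values("start", ascending=False).itertuples():
            seq = seq[: r.start - 1] + seq[r.end :]
        contigs[contig] = seq
    return GenomeAssembly(assembly.genome_id, contigs)


def write_panel(
    outdir: str | Path,
    assemblies: list[GenomeAssembly],
    truth: SyntheticTruth,
) -> None:
    """Write per-strain FASTA plus the truth tables as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for asm in assemblies:
        asm.to_fasta(outdir / f"{asm.genome_id}.fasta")
    write_tsv(truth.genes.drop(columns=["sequence"]), outdir / "truth_genes.tsv")
    write_tsv(truth.placements, outdir / "truth_placements.tsv")
    write_fasta(
        outdir / "gene_sequences.fasta",
        dict(zip(truth.genes["gene_id"], truth.genes["sequence"])),
    )
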