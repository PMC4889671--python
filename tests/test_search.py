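"""Translated search: six-frame translation, local alignment, bit
scores, best-hit selection, tabular parsing."""

import math

import numpy as np
import pytest

from pannovel.io import GenomeAssembly, revcomp
from pannovel.search import (
    DEFAULT_SCHEME,
    ScoringScheme,
    best_genome_hit,
    local_align,
    raw_to_bitscore,
    read_tabular_hits,
    six_frame_translate,
    write_tabular_hits,
)

from _oracles import six_frame_best_score_oracle, sw_affine_oracle, translate_oracle

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestSixFrameTranslate:
    @pytest.mark.parametrize(
        "dna,frame,expected",
        [
            ("ATGAAA", 1, "MK"),
            ("TTTCAT", -1, "MK"),  # reverse-complement symmetry
            ("ATGAAAC", 1, "MK"),  # trailing partial codon dropped
            ("NNNATG", 1, "XM"),   # N codons translate to X
        ],
    )
    def test_examples(self, dna, frame, expected):
        assert six_frame_translate(dna)[frame] == expected

    def test_empty_sequence_gives_six_empty_peptides(self):
        frames = six_frame_translate("")
        assert set(frames) == {1, 2, 3, -1, -2, -3}
        assert all(p == "" for p in frames.values())

    def test_matches_codon_table_oracle_on_random_sequence(self, rng):
        dna = random_dna(rng, 300)
        frames = six_frame_translate(dna)
        assert frames[1] == translate_oracle(dna)
        assert frames[2] == translate_oracle(dna[1:])
        assert frames[-1] == translate_oracle(revcomp(dna))


class TestLocalAlign:
    def test_identical_short_peptide_scores_diagonal_sum(self):
        # BLOSUM62: M=5, K=5, T=5 on the diagonal
        score, qiv, siv = local_align("MKT", "MKT")
        assert score == 15
        assert qiv == (0, 3) and siv == (0, 3)

    def test_empty_subject_scores_zero(self):
        assert local_align("MKT", "")[0] == 0.0

    def test_invalid_query_symbol_raises(self):
        with pytest.raises(ValueError):
            local_align("MK7", "MKT")

    def test_x_scores_zero_against_everything(self):
        mat = DEFAULT_SCHEME.substitution_matrix
        assert all(mat["X", aa] == 0 for aa in AA)

    def test_matches_brute_force_dp_on_random_pairs(self, rng):
        scheme = DEFAULT_SCHEME
        mat = scheme.substitution_matrix
        for _ in range(50):
            q = "".join(rng.choice(list(AA), size=rng.integers(3, 13)))
            s = "".join(rng.choice(list(AA), size=rng.integers(1, 13)))
            expected = sw_affine_oracle(q, s, mat, scheme.gap_open, scheme.gap_extend)
            assert local_align(q, s, scheme)[0] == expected


class TestBitScore:
    def test_zero_raw_score(self):
        assert raw_to_bitscore(0) == pytest.approx(-math.log(0.041) / math.log(2), abs=1e-9)
        assert raw_to_bitscore(0) == pytest.approx(4.61, abs=0.01)

    def test_raw_fifteen(self):
        assert raw_to_bitscore(15) == pytest.approx(10.39, abs=0.01)

    def test_monotone_in_raw_score(self):
        assert raw_to_bitscore(10) < raw_to_bitscore(20)

    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            ScoringScheme(lam=-1)
        with pytest.raises(ValueError):
            ScoringScheme(gap_open=0)


class TestBestGenomeHit:
    def test_planted_gene_recovered_with_overlapping_interval(self, default_panel):
        cfg, assemblies, truth = default_panel
        genes = truth.genes.set_index("gene_id")
        focal = cfg.focal_id
        asm = next(a for a in assemblies if a.genome_id == focal)
        place = truth.placements
        row = place[(place.strain == focal) & (place.gene_id == "core0000")].iloc[0]
        pep = six_frame_translate(genes.loc["core0000", "sequence"])[1].rstrip("*")
        hit = best_genome_hit(pep, "core0000", asm)
        assert hit is not None
        assert hit.contig_id == row.contig
        # hit interval overlaps the true gene interval
        assert max(hit.subject_start, row.start) <= min(hit.subject_end, row.end)

    def test_reverse_strand_gene_reports_negative_frame(self, default_panel):
        cfg, assemblies, truth = default_panel
        genes = truth.genes.set_index("gene_id")
        minus = truth.placements[
            (truth.placements.strain == cfg.reference_id) & (truth.placements.strand == "-")
        ].iloc[0]
        pep = six_frame_translate(genes.loc[minus.gene_id, "sequence"])[1].rstrip("*")
        ref = assemblies[0]
        hit = best_genome_hit(pep, minus.gene_id, ref)
        assert hit is not None
        assert hit.frame < 0
        assert max(hit.subject_start, minus.start) <= min(hit.subject_end, minus.end)

    def test_random_query_below_floor_returns_none(self, rng):
        # tiny genome: noise scores sit well below the default floor
        for _ in range(20):
            genome = GenomeAssembly("g", {"c": random_dna(rng, 400)})
            query = "".join(rng.choice(list(AA), size=30))
            assert best_genome_hit(query, "q", genome) is None

    def test_planted_gene_outscores_genome_without_it(self, rng):
        """A gene's own genome must beat a genome lacking the gene
        (repeated over many random constructions)."""
        scheme = DEFAULT_SCHEME
        for _ in range(100):
            bg1, bg2 = random_dna(rng, 500), random_dna(rng, 500)
            gene = "ATG" + "".join(
                rng.choice([c for c in _codons() if c not in ("TAA", "TAG", "TGA")], size=40)
            ) + "TAA"
            pos = int(rng.integers(0, 400))
            with_gene = GenomeAssembly("w", {"c": bg1[:pos] + gene + bg1[pos:]})
            without = GenomeAssembly("wo", {"c": bg2})
            pep = six_frame_translate(gene)[1].rstrip("*")
            hit_in = best_genome_hit(pep, "q", with_gene, scheme, raw_floor=0.0)
            hit_out = best_genome_hit(pep, "q", without, scheme, raw_floor=0.0)
            out_bits = hit_out.bit_score if hit_out else 0.0
            assert hit_in is not None and hit_in.bit_score > out_bits

    def test_internal_search_equals_brute_force_six_frame_dp(self, rng):
        """Exhaustive-DP equivalence on small random genomes, with and
        without planted genes."""
        scheme = DEFAULT_SCHEME
        mat = scheme.substitution_matrix
        for i in range(10):
            dna = random_dna(rng, 600)
            query = "".join(rng.choice(list(AA), size=20))
            if i % 2 == 0:  # plant a diverged copy of the query
                insert = "".join(
                    {"A": "GCT", "C": "TGT"}.get(a, "GCT") for a in query[:10]
                )
                dna = dna[:200] + insert + dna[200:]
            genome = GenomeAssembly("g", {"c": dna})
            hit = best_genome_hit(query, "q", genome, scheme, raw_floor=0.0)
            got = hit.raw_score if hit else 0.0
            expected = six_frame_best_score_oracle(query, dna, mat, scheme.gap_open, scheme.gap_extend)
            assert got == expected


def _codons():
    return [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]


class TestTabularHits:
    def _write(self, tmp_path, rows):
        path = tmp_path / "hits.tsv"
        path.write_text("\n".join("\t".join(map(str, r)) for r in rows) + "\n")
        return path

    def test_bitscore_passthrough(self, tmp_path):
        row = ["q1", "s1", 98.0, 50, 1, 0, 1, 50, 100, 249, 1e-20, 100.0]
        hits = read_tabular_hits(self._write(tmp_path, [row]))
        assert len(hits) == 1 and hits[0].bit_score == 100.0

    def test_best_hit_per_query_genome_retained(self, tmp_path):
        rows = [
            ["q1", "s1", 90, 50, 1, 0, 1, 50, 100, 249, 1e-20, 80.0],
            ["q1", "s1", 95, 50, 1, 0, 1, 50, 300, 449, 1e-25, 95.0],
        ]
        hits = read_tabular_hits(self._write(tmp_path, rows))
        assert len(hits) == 1 and hits[0].bit_score == 95.0

    def test_minus_strand_coordinates_normalized(self, tmp_path):
        row = ["q1", "s1", 98, 50, 1, 0, 1, 50, 900, 700, 1e-20, 60.0]
        hit = read_tabular_hits(self._write(tmp_path, [row]))[0]
        assert (hit.subject_start, hit.subject_end) == (700, 900)
        assert hit.frame < 0

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("q1\ts1\tnot-enough-columns\n")
        with pytest.raises(ValueError, match="line 1"):
            read_tabular_hits(path)

    def test_write_read_round_trip(self, tmp_path, rng):
        genome = GenomeAssembly("g", {"c": random_dna(rng, 200)})
        rows = [["qq", "c", 98, 50, 1, 0, 1, 50, 10, 60, 1e-5, 42.5]]
        path = self._write(tmp_path, rows)
        hits = read_tabular_hits(path)
        out = tmp_path / "out.tsv"
        write_tabular_hits(hits, out)
        again = read_tabular_hits(out)
        assert again[0].bit_score == hits[0].bit_score
        assert (again[0].subject_start, again[0].subject_end) == (10, 60)
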