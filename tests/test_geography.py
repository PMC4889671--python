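"""N50, subtelomere classification, missing genes, nonsyntenic
homologs, clusters, and reference-guided scaffolding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pannovel.annotation import AnnotationSet, GeneModel
from pannovel.geography import (
    GeographyParams,
    detect_gene_clusters,
    detect_missing_genes,
    find_nonsyntenic_homologs,
    n50,
    placements_to_frame,
    reference_guided_scaffold,
    subtelomeric_classify,
)
from pannovel.io import GenomeAssembly, revcomp
from pannovel.search import six_frame_translate
from pannovel.synth import SyntheticConfig, excise_genes, generate_strain_panel

from _oracles import n50_scan_oracle


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestN50:
    @pytest.mark.parametrize("lengths,expected", [([10, 5, 3, 2], 10), ([7, 7, 7], 7)])
    def test_examples(self, lengths, expected):
        assert n50(lengths) == expected

    def test_matches_scan_oracle_on_random_lists(self, rng):
        for _ in range(100):
            lengths = [int(x) for x in rng.integers(1, 1000, size=rng.integers(1, 30))]
            assert n50(lengths) == n50_scan_oracle(lengths)

    @given(st.lists(st.integers(1, 10**6), min_size=1, max_size=40), st.integers(1, 50))
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariance_and_linear_scaling(self, lengths, c):
        shuffled = list(reversed(sorted(lengths)))
        assert n50(lengths) == n50(shuffled)
        assert n50([c * x for x in lengths]) == c * n50(lengths)

    def test_empty_or_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            n50([])
        with pytest.raises(ValueError):
            n50([5, 0])


class TestSubtelomericClassify:
    PARAMS = GeographyParams(subtelomere_span=50_000)

    def test_gene_near_left_end(self):
        assert subtelomeric_classify(30_000, 31_000, 500_000, self.PARAMS)

    def test_gene_in_the_middle(self):
        assert not subtelomeric_classify(249_000, 251_000, 500_000, self.PARAMS)

    def test_boundary_exactly_at_span_is_inclusive(self):
        # nearest-end distance exactly 50,000
        assert subtelomeric_classify(50_001, 60_000, 500_000, self.PARAMS)
        assert not subtelomeric_classify(50_002, 60_000, 500_000, self.PARAMS)

    def test_gene_near_right_end(self):
        assert subtelomeric_classify(460_000, 461_000, 500_000, self.PARAMS)


@pytest.fixture(scope="module")
def deletion_fixture():
    cfg = SyntheticConfig(seed=4)
    assemblies, truth = generate_strain_panel(cfg)
    ref_asm = assemblies[0]
    full = truth.annotation_for(cfg.reference_id)
    core = [m for m in full.models if m.gene_id.startswith("core")][:12]
    sub_ann = AnnotationSet(
        cfg.reference_id,
        [GeneModel(m.gene_id, m.contig, m.start, m.end, m.strand, m.status) for m in core],
    )
    deleted = [m.gene_id for m in core[:5]]
    target = excise_genes(ref_asm, truth, set(deleted))
    target.genome_id = "target"
    params = GeographyParams(
        subtelomere_span=cfg.subtelomere_span, cluster_max_gap=2000, missing_bit_floor=30.0
    )
    return cfg, truth, assemblies, ref_asm, sub_ann, deleted, target, params


class TestMissingGenes:
    def test_deleted_genes_exactly_reported(self, deletion_fixture):
        cfg, truth, assemblies, ref_asm, sub_ann, deleted, target, params = deletion_fixture
        missing = detect_missing_genes(sub_ann, ref_asm, target, params=params)
        assert sorted(missing) == sorted(deleted)

    def test_self_search_reports_nothing_missing(self, deletion_fixture):
        cfg, truth, assemblies, ref_asm, sub_ann, deleted, target, params = deletion_fixture
        assert detect_missing_genes(sub_ann, ref_asm, ref_asm, params=params) == []

    def test_floor_monotonicity(self, deletion_fixture):
        """Raising the floor can only grow the missing set."""
        cfg, truth, assemblies, ref_asm, sub_ann, deleted, target, params = deletion_fixture
        hits = {}  # reuse scores via the hits shortcut: compute once
        from pannovel.search import best_genome_hit

        for m in sub_ann.models:
            pep = six_frame_translate(m.sequence(ref_asm))[1].rstrip("*")
            h = best_genome_hit(pep, m.gene_id, target, raw_floor=0.0)
            hits[m.gene_id] = h.bit_score if h else 0.0
        low = set(detect_missing_genes(sub_ann, ref_asm, target, params=params, hits=hits))
        high_params = GeographyParams(
            subtelomere_span=params.subtelomere_span, missing_bit_floor=80.0
        )
        high = set(detect_missing_genes(sub_ann, ref_asm, target, params=high_params, hits=hits))
        assert low <= high


class TestNonsyntenicHomologs:
    def _panel(self, relocate=True, reciprocal=True):
        cfg = SyntheticConfig(seed=4)
        _, truth = generate_strain_panel(cfg)
        genes = truth.genes.set_index("gene_id")
        ids = [g for g in genes.index if g.startswith("core")][:8]
        prot = lambda g: six_frame_translate(genes.loc[g, "sequence"])[1].rstrip("*")
        prots_a = {g: prot(g) for g in ids}
        prots_b = dict(prots_a)
        ann_a = AnnotationSet(
            "A", [GeneModel(g, "chrI", 1000 * i + 1, 1000 * i + 500, "+") for i, g in enumerate(ids)]
        )
        models_b = []
        for i, g in enumerate(ids):
            if relocate and g == ids[3]:
                models_b.append(GeneModel(g, "chrII", 501, 1000, "+"))
            else:
                models_b.append(GeneModel(g, "chrI", 1000 * i + 1, 1000 * i + 500, "+"))
        ann_b = AnnotationSet("B", models_b)
        if not reciprocal:
            # make b's best hit for ids[3] point elsewhere by removing it
            del prots_b[ids[3]]
            ann_b = AnnotationSet("B", [m for m in models_b if m.gene_id != ids[3]])
        return ids, ann_a, prots_a, ann_b, prots_b

    def test_relocated_gene_reported_nonsyntenic(self):
        ids, ann_a, prots_a, ann_b, prots_b = self._panel()
        pairs = find_nonsyntenic_homologs(ann_a, prots_a, ann_b, prots_b)
        assert (ids[3], ids[3]) in pairs

    def test_identical_neighborhood_not_reported(self):
        ids, ann_a, prots_a, ann_b, prots_b = self._panel(relocate=False)
        assert find_nonsyntenic_homologs(ann_a, prots_a, ann_b, prots_b) == []

    def test_one_directional_best_hit_not_reported(self):
        ids, ann_a, prots_a, ann_b, prots_b = self._panel(reciprocal=False)
        pairs = find_nonsyntenic_homologs(ann_a, prots_a, ann_b, prots_b)
        assert all(a != ids[3] for a, _ in pairs)


class TestGeneClusters:
    def _cluster_panel(self):
        cfg = SyntheticConfig(
            seed=6, n_novel_genes=3, n_clusters=1, cluster_size=3,
            novel_subtelomeric_fraction=1.0,
        )
        assemblies, truth = generate_strain_panel(cfg)
        carriers = truth.genes.loc[truth.genes.gene_id == "novel000", "carriers"].iloc[0]
        strain = carriers.split(";")[0]
        asm = next(a for a in assemblies if a.genome_id == strain)
        ann = truth.annotation_for(strain)
        params = GeographyParams(subtelomere_span=cfg.subtelomere_span, cluster_max_gap=2000)
        return truth, strain, asm, ann, params

    def test_planted_cluster_recovered_with_subtelomeric_flag(self):
        truth, strain, asm, ann, params = self._cluster_panel()
        novel = {g for g in truth.members_of(strain) if g.startswith("novel")}
        calls = detect_gene_clusters(novel, ann, asm.contig_lengths(), params)
        assert len(calls) == 1
        assert sorted(calls[0].members) == sorted(novel)
        assert calls[0].subtelomeric

    def test_distant_genes_do_not_cluster(self):
        ann = AnnotationSet(
            "g",
            [
                GeneModel("n1", "c", 1000, 1500, "+"),
                GeneModel("n2", "c", 150_000, 150_500, "+"),
            ],
        )
        params = GeographyParams(subtelomere_span=5000, cluster_max_gap=20_000)
        assert detect_gene_clusters({"n1", "n2"}, ann, {"c": 200_000}, params) == []

    def test_singleton_never_clustered(self):
        ann = AnnotationSet("g", [GeneModel("n1", "c", 1000, 1500, "+")])
        params = GeographyParams(subtelomere_span=5000)
        assert detect_gene_clusters({"n1"}, ann, {"c": 100_000}, params) == []

    def test_no_gene_in_two_clusters(self):
        ann = AnnotationSet(
            "g",
            [GeneModel(f"n{i}", "c", 1000 * i + 1, 1000 * i + 400, "+") for i in range(6)],
        )
        params = GeographyParams(subtelomere_span=5000, cluster_max_gap=2000)
        calls = detect_gene_clusters({f"n{i}" for i in range(6)}, ann, {"c": 100_000}, params)
        members = [g for c in calls for g in c.members]
        assert len(members) == len(set(members))


class TestScaffolding:
    def test_shredded_chromosome_reassembled(self, rng):
        ref_seq = random_dna(rng, 8000)
        ref = GenomeAssembly("ref", {"chrI": ref_seq})
        pieces = [ref_seq[i * 2000 : (i + 1) * 2000] for i in range(4)]
        pieces[2] = revcomp(pieces[2])
        contigs = GenomeAssembly(
            "asm", {"c3": pieces[2], "c1": pieces[0], "c4": pieces[3], "c2": pieces[1]}
        )
        placements = {p.contig: p for p in reference_guided_scaffold(contigs, ref)}
        assert [placements[f"c{i}"].order for i in (1, 2, 3, 4)] == [0, 1, 2, 3]
        assert placements["c3"].strand == "-"
        assert all(placements[f"c{i}"].strand == "+" for i in (1, 2, 4))

    def test_unshuffled_genome_identity_placement(self, rng):
        ref = GenomeAssembly("ref", {"chrI": random_dna(rng, 3000), "chrII": random_dna(rng, 3000)})
        same = GenomeAssembly("asm", dict(ref.contigs))
        placements = {p.contig: p for p in reference_guided_scaffold(same, ref)}
        for chrom in ref.contigs:
            assert placements[chrom].chromosome == chrom
            assert placements[chrom].order == 0
            assert placements[chrom].strand == "+"

    def test_random_contig_unplaced_never_dropped(self, rng):
        ref = GenomeAssembly("ref", {"chrI": random_dna(rng, 3000)})
        contigs = GenomeAssembly(
            "asm", {"good": ref.contigs["chrI"][:1500], "junk": random_dna(rng, 1000)}
        )
        placements = {p.contig: p for p in reference_guided_scaffold(contigs, ref)}
        assert placements["junk"].chromosome is None
        assert placements["good"].chromosome == "chrI"
        assert len(placements) == 2

    def test_placements_frame_has_all_contigs(self, rng):
        ref = GenomeAssembly("ref", {"chrI": random_dna(rng, 2000)})
        contigs = GenomeAssembly("asm", {"a": ref.contigs["chrI"][:900]})
        df = placements_to_frame(reference_guided_scaffold(contigs, ref))
        assert list(df["contig"]) == ["a"]
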