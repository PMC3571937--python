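import numpy as np
import pytest

from syntenic.alignment import AlignmentParams
from syntenic.genome_io import (
    CDSFeature,
    FixtureSpec,
    GenomeRecord,
    PlantedGene,
    make_fixture_genome,
    mutate_protein,
    random_protein,
)
from syntenic.search import SearchParams
from syntenic.synteny import (
    MAX_GENOMES,
    Segment,
    SegmentGene,
    _PairScorer,
    build_reference_colors,
    extract_segment,
    propagate_colors,
    run_synteny,
)

from _oracles import component_partition


def _segment(proteins):
    genes = [
        SegmentGene(
            feature=CDSFeature(f"g{i}", "p", 1000 * i, 1000 * i + 300, 1),
            protein=p,
        )
        for i, p in enumerate(proteins)
    ]
    return Segment(
        accession="SEG", organism="o", window_start=0, window_length=15000,
        genome_length=30000, circular=False, genes=genes,
    )


class TestExtractSegment:
    def test_centered_window_on_linear_replicon(self):
        g = GenomeRecord("L1", "o", "A" * 30000)
        seg = extract_segment(g, 15000, 15000)
        assert (seg.window_start, seg.window_end) == (7500, 22500)
        assert seg.window_length == 15000

    def test_window_clipped_at_linear_edge(self):
        g = GenomeRecord("L2", "o", "A" * 10000)
        seg = extract_segment(g, 2000, 15000)
        assert (seg.window_start, seg.window_end) == (0, 9500)
        assert seg.window_length == 9500

    def test_circular_window_wraps_with_exact_width(self):
        g = GenomeRecord("C1", "o", "A" * 20000, is_circular=True)
        seg = extract_segment(g, 100, 15000)
        assert seg.window_length == 15000
        # oracle: slice the doubled sequence at (100 - 7500) mod 20000
        assert seg.window_start == (100 - 7500) % 20000 == 12600
        assert seg.display_offset(12600) == 0
        assert seg.display_offset(7599) == 14999

    def test_genes_overlapping_wrap_window_are_collected(self, cluster_proteins):
        p = cluster_proteins["P4"]
        spec = FixtureSpec(
            "C2", "o", 20000, circular=True,
            genes=(PlantedGene("near_ori", p, 90), PlantedGene("far", p, 9000)),
        )
        genome, _ = make_fixture_genome(spec, 21)
        seg = extract_segment(genome, 100, 15000)
        assert [g.feature.locus_tag for g in seg.genes] == ["near_ori"]

    def test_window_never_exceeds_replicon(self):
        g = GenomeRecord("S1", "o", "A" * 4000, is_circular=True)
        assert extract_segment(g, 100, 15000).window_length == 4000


class TestReferenceColors:
    def test_related_pair_shares_color_unrelated_does_not(self, align_params):
        rng = np.random.default_rng(31)
        a = random_protein(rng, 80)
        b = mutate_protein(rng, a, 0.7)  # well above 30 % normalized
        c = random_protein(rng, 80)
        seg = _segment([a, b, c])
        colors = build_reference_colors(seg, 30.0, align_params)
        cols = [g.color for g in seg.genes]
        assert cols[0] == cols[1] != cols[2]
        assert sorted(set(cols)) == [1, 2]

    def test_all_unrelated_get_distinct_colors(self, align_params):
        rng = np.random.default_rng(32)
        seg = _segment([random_protein(rng, 60) for _ in range(5)])
        build_reference_colors(seg, 30.0, align_params)
        assert [g.color for g in seg.genes] == [1, 2, 3, 4, 5]

    def test_identical_paralogs_share_color(self, align_params):
        rng = np.random.default_rng(33)
        p = random_protein(rng, 60)
        seg = _segment([p, p])
        build_reference_colors(seg, 100.0, align_params)
        assert seg.genes[0].color == seg.genes[1].color == 1

    @pytest.mark.parametrize("n", range(2, 9))
    def test_partition_equals_graph_components(self, n, align_params):
        # families of diverged copies around the threshold, checked against
        # networkx connected components of the same thresholded score matrix
        rng = np.random.default_rng(300 + n)
        bases = [random_protein(rng, 50) for _ in range(max(1, n // 2))]
        prots = [
            mutate_protein(rng, bases[int(rng.integers(len(bases)))], rng.uniform(0.3, 0.95))
            for _ in range(n)
        ]
        seg = _segment(prots)
        scorer = _PairScorer(align_params)
        build_reference_colors(seg, 30.0, align_params, scorer=scorer)
        expected = component_partition(prots, scorer.norm, 30.0)
        got = {}
        for i, g in enumerate(seg.genes):
            got.setdefault(g.color, set()).add(i)
        assert sorted(got.values(), key=min) == expected

    def test_colors_assigned_left_to_right(self, align_params):
        rng = np.random.default_rng(34)
        a, b = random_protein(rng, 60), random_protein(rng, 60)
        seg = _segment([a, b, a])  # paralog of gene 0 sits at position 2
        build_reference_colors(seg, 30.0, align_params)
        assert [g.color for g in seg.genes] == [1, 2, 1]


class TestPropagation:
    def test_exact_copy_inherits_reference_color(self, align_params):
        rng = np.random.default_rng(41)
        ref_prots = [random_protein(rng, 70) for _ in range(3)]
        ref = _segment(ref_prots)
        colors = build_reference_colors(ref, 30.0, align_params)
        other = _segment([ref_prots[1]])
        propagate_colors(colors, ref, other, 30.0, align_params)
        assert other.genes[0].color == ref.genes[1].color
        assert other.genes[0].norm_score == 100.0
        assert other.syntenic

    def test_fusion_inherits_better_scoring_half(self, align_params):
        rng = np.random.default_rng(42)
        p_short = random_protein(rng, 50)
        p_long = random_protein(rng, 120)
        ref = _segment([p_short, p_long])
        colors = build_reference_colors(ref, 30.0, align_params)
        other = _segment([p_short + p_long])
        propagate_colors(colors, ref, other, 30.0, align_params)
        # the longer parent covers more of the fusion, hence scores higher
        assert other.genes[0].color == ref.genes[1].color

    def test_no_match_flags_segment_non_syntenic(self, align_params):
        rng = np.random.default_rng(43)
        ref = _segment([random_protein(rng, 70)])
        colors = build_reference_colors(ref, 30.0, align_params)
        other = _segment([random_protein(rng, 70)])
        propagate_colors(colors, ref, other, 30.0, align_params)
        assert other.genes[0].color is None
        assert not other.syntenic

    def test_threshold_100_requires_identical_self_match(self, align_params):
        rng = np.random.default_rng(44)
        p = random_protein(rng, 70)
        ref = _segment([p])
        colors = build_reference_colors(ref, 100.0, align_params)
        near = _segment([mutate_protein(rng, p, 0.97)])
        propagate_colors(colors, ref, near, 100.0, align_params)
        assert near.genes[0].color is None
        exact = _segment([p])
        propagate_colors(colors, ref, exact, 100.0, align_params)
        assert exact.genes[0].color == 1

    def test_vanishing_threshold_colors_any_positive_score(self, align_params):
        rng = np.random.default_rng(45)
        ref = _segment([random_protein(rng, 70)])
        colors = build_reference_colors(ref, 1e-9, align_params)
        other = _segment([random_protein(rng, 70)])
        propagate_colors(colors, ref, other, 1e-9, align_params)
        assert other.genes[0].color == 1  # any positive local score suffices


class TestRunSynteny:
    def test_planted_cluster_propagates_all_colors(self, cluster_report):
        assert [seg.accession for seg in cluster_report.rows] == [
            "SYN001", "SYN002", "SYN003",
        ]
        ref = cluster_report.rows[0]
        by_tag = {g.feature.locus_tag: g.color for g in ref.genes}
        assert by_tag["p2"] == by_tag["p2b"]  # paralogs share one color
        assert len({by_tag[t] for t in ("p1", "p2", "p3", "p4", "p5")}) == 5
        for seg in cluster_report.rows[1:2]:  # SYN002: full cluster
            colors = {g.feature.locus_tag: g.color for g in seg.genes}
            for tag in ("p1", "p2", "p2b", "p3", "p4", "p5"):
                assert colors[tag] == by_tag[tag]
        fusion_seg = cluster_report.rows[2]
        fusion = next(g for g in fusion_seg.genes if g.feature.locus_tag == "p45")
        assert fusion.color in (by_tag["p4"], by_tag["p5"])

    def test_cluster_free_genome_in_not_found(self, cluster_report):
        assert cluster_report.not_found == [("SYN004", "Vacua quarta")]

    def test_single_genome_degenerate_star(self, cluster_proteins, cluster_genomes):
        report = run_synteny(cluster_proteins["P1"], cluster_genomes[:1])
        assert len(report.rows) == 1
        assert all(g.color is not None or g.norm_score is None for g in report.rows[0].genes)

    def test_query_hitless_everywhere(self, cluster_genomes):
        rng = np.random.default_rng(51)
        stranger = random_protein(rng, 90)
        report = run_synteny(stranger, cluster_genomes[3:])
        assert report.rows == []
        assert report.not_found == [("SYN004", "Vacua quarta")]

    def test_genome_cap_enforced_before_computation(self, cluster_proteins):
        genomes = [
            GenomeRecord(f"T{i:03d}", "o", "ACGT" * 30) for i in range(MAX_GENOMES + 1)
        ]
        with pytest.raises(ValueError, match="at most 100"):
            run_synteny(cluster_proteins["P1"], genomes)

    def test_duplicate_accessions_rejected(self, cluster_proteins):
        genomes = [GenomeRecord("T1", "o", "ACGT" * 30)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            run_synteny(cluster_proteins["P1"], genomes)

    def test_colors_independent_of_non_reference_order(
        self, cluster_proteins, cluster_genomes
    ):
        a = run_synteny(cluster_proteins["P1"], cluster_genomes)
        b = run_synteny(cluster_proteins["P1"], cluster_genomes[::-1])
        cols_a = {
            seg.accession: [(g.feature.locus_tag, g.color) for g in seg.genes]
            for seg in a.rows
        }
        cols_b = {
            seg.accession: [(g.feature.locus_tag, g.color) for g in seg.genes]
            for seg in b.rows
        }
        assert cols_a == cols_b

    def test_window_length_conservation(self, cluster_report):
        for seg in cluster_report.rows:
            expected = min(15000, seg.genome_length)
            if 0 <= seg.anchor.center_bp - expected // 2 and (
                seg.anchor.center_bp + expected // 2 <= seg.genome_length
            ):
                assert seg.window_length == expected
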