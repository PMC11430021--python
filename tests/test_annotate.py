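import numpy as np
import pandas as pd
import pytest

from rloopkit.annotate import (FEATURES, FeatureMap, _IDX, assign_feature,
                               build_feature_map, downstream_window,
                               gene_length_density, median_lengths_by_set,
                               obs_exp_enrichment, overlap_gene_classes,
                               promoter_window, stratum_proportions)
from rloopkit.classify import RLoopCall
from rloopkit.io import Gene, GenomeModel, IntervalRecord


def loop(chrom, start, end, cls="unstranded", strand=None):
    return RLoopCall(chrom, start, end, cls, strand)


class TestWindows:
    def test_plus_promoter(self):
        g = Gene("g", "chr1", "+", 10_000, 20_000)
        assert promoter_window(g) == (7_500, 10_500)

    def test_plus_downstream(self):
        g = Gene("g", "chr1", "+", 10_000, 20_000)
        assert downstream_window(g) == (19_500, 22_500)

    def test_minus_promoter_mirrors(self):
        # '-' gene spanning [5000, 8000): TSS at the right end
        g = Gene("g", "chr1", "-", 5_000, 8_000)
        assert promoter_window(g) == (7_500, 10_500)

    def test_minus_downstream_mirrors(self):
        g = Gene("g", "chr1", "-", 5_000, 8_000)
        assert downstream_window(g) == (2_500, 5_500)


class TestFeatureMap:
    def test_priority_promoter_over_body(self, tiny_genome):
        fmap = build_feature_map(tiny_genome)
        # g1 '+' gene [10000, 20000): promoter [7500, 10500) wins over intron
        assert fmap.label_at("chr1", 10_200) == "promoter_tss"
        assert fmap.label_at("chr1", 15_000) == "intron"
        assert fmap.label_at("chr1", 20_100) == "downstream_tts"
        assert fmap.label_at("chr1", 80_000) == "intergenic"

    def test_pseudogene_label(self, tiny_genome):
        fmap = build_feature_map(tiny_genome)
        assert fmap.label_at("chr2", 6_000) == "pseudogene"

    def test_exons_used_when_given(self, tiny_genome):
        fmap = build_feature_map(tiny_genome, exons=[IntervalRecord("chr1", 12_000, 13_000)])
        assert fmap.label_at("chr1", 12_500) == "exon"
        assert fmap.label_at("chr1", 14_000) == "intron"

    def test_window_clipped_at_boundary(self):
        genome = GenomeModel({"chr1": 5_000}, [Gene("g", "chr1", "+", 1_000, 4_000)])
        fmap = build_feature_map(genome)  # promoter would start at -1500
        assert fmap.label_at("chr1", 0) == "promoter_tss"
        assert len(fmap.labels["chr1"]) == 5_000

    def test_partition_covers_genome(self, tiny_genome):
        fmap = build_feature_map(tiny_genome)
        assert sum(fmap.feature_bp().values()) == tiny_genome.total_length

    def test_mirror_symmetry(self):
        """Reversing strands and coordinates yields the mirrored map."""
        size = 50_000
        genes = [Gene("a", "chr1", "+", 10_000, 18_000, "protein_coding", 5.0),
                 Gene("b", "chr1", "-", 30_000, 41_000, "pseudogene", 2.0)]
        mirrored = [Gene(g.gene_id, g.chrom,
                         "-" if g.strand == "+" else "+",
                         size - g.end, size - g.start, g.biotype, g.expression)
                    for g in genes]
        f1 = build_feature_map(GenomeModel({"chr1": size}, genes))
        f2 = build_feature_map(GenomeModel({"chr1": size}, mirrored))
        np.testing.assert_array_equal(f1.labels["chr1"], f2.labels["chr1"][::-1])


class TestAssign:
    def test_midpoint_rules(self, tiny_genome):
        fmap = build_feature_map(tiny_genome)
        assert assign_feature(loop("chr1", 9_000, 11_000), fmap) == "promoter_tss"
        assert assign_feature(loop("chr1", 14_000, 16_000), fmap) == "intron"
        assert assign_feature(loop("chr1", 70_000, 71_000), fmap) == "intergenic"


class TestObsExp:
    def test_whole_genome_single_feature_ratio_one(self):
        genome = GenomeModel({"chr1": 100_000})
        fmap = build_feature_map(genome)  # everything intergenic
        loops = [loop("chr1", i * 1000, i * 1000 + 100) for i in range(50)]
        rows = obs_exp_enrichment(loops, fmap, genome, n_boot=50, seed=0)
        row = next(r for r in rows if r.feature == "intergenic")
        assert row.ratio == pytest.approx(1.0)

    def test_arithmetic_example(self):
        """1 Mb genome, 50 kb labelled promoter, 20/100 loops inside ->
        expected 5, ratio 4."""
        labels = np.full(1_000_000, _IDX["intergenic"], dtype=np.int8)
        labels[:50_000] = _IDX["promoter_tss"]
        fmap = FeatureMap({"chr1": labels})
        genome = GenomeModel({"chr1": 1_000_000})
        loops = [loop("chr1", i * 100, i * 100 + 50) for i in range(20)]          # mid < 50k
        loops += [loop("chr1", 100_000 + i * 100, 100_000 + i * 100 + 50) for i in range(80)]
        rows = obs_exp_enrichment(loops, fmap, genome, n_boot=50, seed=0)
        row = next(r for r in rows if r.feature == "promoter_tss")
        assert row.observed == 20
        assert row.expected == pytest.approx(5.0)
        assert row.ratio == pytest.approx(4.0)

    def test_empty_feature_ratio_zero(self):
        labels = np.full(10_000, _IDX["intergenic"], dtype=np.int8)
        labels[:1_000] = _IDX["exon"]
        fmap = FeatureMap({"chr1": labels})
        genome = GenomeModel({"chr1": 10_000})
        loops = [loop("chr1", 5_000, 5_100)]
        rows = obs_exp_enrichment(loops, fmap, genome, n_boot=20, seed=0)
        row = next(r for r in rows if r.feature == "exon")
        assert row.observed == 0 and row.ratio == 0.0

    def test_no_loops_errors(self, tiny_genome):
        with pytest.raises(ValueError, match="no R-loops"):
            obs_exp_enrichment([], build_feature_map(tiny_genome), tiny_genome)

    def test_uniform_calibration_small(self, tiny_genome, rng):
        fmap = build_feature_map(tiny_genome)
        total = tiny_genome.total_length
        sizes = list(tiny_genome.chrom_sizes.items())
        loops = []
        for _ in range(400):
            flat = int(rng.integers(0, total))
            chrom, off = ("chr1", flat) if flat < 100_000 else ("chr2", flat - 100_000)
            loops.append(loop(chrom, max(off - 50, 0), min(off + 50, tiny_genome.chrom_sizes[chrom])))
        rows = obs_exp_enrichment(loops, fmap, tiny_genome, n_boot=300, seed=1)
        for r in rows:
            if r.expected >= 5:
                assert r.ci_low <= 1.0 <= r.ci_high


def expressed_genome() -> GenomeModel:
    genes = [Gene(f"g{i}", "chr1", "+", i * 10_000, i * 10_000 + 2_000 + 500 * i,
                  "protein_coding", float(2 + i))
             for i in range(9)]
    return GenomeModel({"chr1": 200_000}, genes)


class TestGeneClasses:
    def test_tertiles_three_each(self):
        df = overlap_gene_classes(expressed_genome(), [loop("chr1", 0, 100)])
        assert df["stratum"].value_counts().to_dict() == {"low": 3, "mid": 3, "high": 3}

    def test_flags(self):
        genome = expressed_genome()
        stranded = [RLoopCall("chr1", 500, 900, "stranded", "+")]  # inside g0
        df = overlap_gene_classes(genome, stranded)
        row = df.set_index("gene_id").loc["g0"]
        assert row["has_stranded"] and not row["has_unstranded"]

    def test_extended_span_counts_promoter_overlap(self):
        genome = expressed_genome()
        # loop upstream of g1 (starts at 10000), inside its promoter window
        loops = [RLoopCall("chr1", 8_000, 8_400, "unstranded", None)]
        df = overlap_gene_classes(genome, loops).set_index("gene_id")
        assert df.loc["g1", "has_unstranded"]

    def test_factor_peaks_flag(self):
        genome = expressed_genome()
        df = overlap_gene_classes(genome, [], factor_peaks=[IntervalRecord("chr1", 100, 200)])
        assert df.set_index("gene_id").loc["g0", "has_factor_peak"]

    def test_no_expressed_genes_errors(self):
        genome = GenomeModel({"chr1": 10_000}, [Gene("g", "chr1", "+", 0, 100,
                                                     "protein_coding", 0.5)])
        with pytest.raises(ValueError, match="expression"):
            overlap_gene_classes(genome, [])

    def test_stratum_proportions_shape(self):
        df = overlap_gene_classes(expressed_genome(), [loop("chr1", 0, 100)])
        props = stratum_proportions(df)
        assert set(props["stratum"]) == {"low", "mid", "high"}
        assert ((props["has_unstranded"] >= 0) & (props["has_unstranded"] <= 1)).all()


class TestGeneLengthDensity:
    def test_no_rloops_all_none(self):
        df = gene_length_density(expressed_genome(), [])
        assert (df["rloop_set"] == "none").all()

    def test_overlapped_gene_not_none(self):
        df = gene_length_density(expressed_genome(),
                                 [RLoopCall("chr1", 500, 900, "stranded", "+")])
        assert df.set_index("gene_id").loc["g0", "rloop_set"] == "stranded_only"

    def test_partition(self):
        loops = [RLoopCall("chr1", 500, 900, "stranded", "+"),
                 RLoopCall("chr1", 700, 1_200, "unstranded", None),
                 RLoopCall("chr1", 20_500, 20_900, "unstranded", None)]
        df = gene_length_density(expressed_genome(), loops)
        assert set(df["rloop_set"]) <= {"none", "stranded_only", "unstranded_only", "both"}
        assert len(df) == 9  # every expressed gene in exactly one set

    def test_long_gene_bias_recovered_from_truth(self):
        """Planted long-gene bias shows up as longer R-loop-bearing genes."""
        from rloopkit.simulate import SimConfig, make_genome, plant_rloops
        cfg = SimConfig(genome=[("chr1", 3_000_000)], n_genes=150,
                        placement_bias="long_genes", n_stranded=20,
                        n_unstranded=20, seed=5)
        genome = make_genome(cfg)
        truth = plant_rloops(genome, cfg)
        rloops = [RLoopCall(t.chrom, t.start, t.end,
                            t.true_class, t.true_strand) for t in truth]
        df = gene_length_density(genome, rloops, expression_floor=0.0)
        med = df.groupby(df["rloop_set"] == "none")["length"].median()
        assert med[False] > med[True]  # with-loop genes longer than loop-free
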