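"""Synthetic-data generators: determinism, planted truth, noise model."""

import numpy as np
import pandas as pd
import pytest

from racenet import simulate
from racenet.core import GeneModel, GenomicInterval
from racenet.pooling import PoolingConfig, assign_pools, min_pool_count
from racenet.simulate import (
    AuxConfig,
    ConfigurationError,
    DupConfig,
    NetworkSpec,
    NoiseConfig,
    SyntheticAnnotation,
    generate_annotation,
    generate_products,
    plant_transcriptome,
    simulate_array_tracks,
    simulate_aux_data,
)
from racenet.validation import classify_splice_junction, junction_duplication

SMALL = dict(n_chroms=1, chrom_len_nt=60_000, n_genes=6)


class TestGenerateAnnotation:
    def test_deterministic_given_seed(self):
        a = generate_annotation(**SMALL, seed=1)
        b = generate_annotation(**SMALL, seed=1)
        assert a.genome == b.genome
        assert [g.locus for g in a.genes] == [g.locus for g in b.genes]
        assert a.primers == b.primers
        pd.testing.assert_frame_equal(a.probes, b.probes)

    def test_probe_count_closed_form(self):
        length = 100_000
        ann = generate_annotation(n_chroms=1, chrom_len_nt=length, n_genes=4, seed=0)
        assert len(ann.probes) == (length - 25) // 17 + 1

    def test_zero_genes_still_tiles_probes(self):
        ann = generate_annotation(n_chroms=1, chrom_len_nt=20_000, n_genes=0, seed=0)
        assert ann.genes == [] and len(ann.probes) > 0

    def test_infeasible_density_raises(self):
        with pytest.raises(ConfigurationError):
            generate_annotation(n_chroms=1, chrom_len_nt=12_000, n_genes=40, seed=0)

    def test_genes_do_not_overlap(self):
        ann = generate_annotation(**SMALL, seed=3)
        loci = sorted((g.locus for g in ann.genes), key=lambda iv: (iv.chrom, iv.start))
        for a, b in zip(loci, loci[1:]):
            assert a.chrom != b.chrom or a.end <= b.start

    def test_primers_inside_aceps_one_per_direction(self):
        from racenet.core import project_exons

        ann = generate_annotation(**SMALL, seed=3)
        for g in ann.genes:
            mine = [p for p in ann.primers if p.gene_id == g.gene_id]
            assert sorted(p.race_type for p in mine) == ["3p", "5p"]
            aceps = project_exons(g).aceps
            for p in mine:
                assert any(a.contains(p.span) for a in aceps)

    def test_multimap_probes_planted_and_detectable(self):
        from racenet.filters import flag_unspecific_probes

        ann = generate_annotation(**SMALL, seed=5, multi_probe_rate=0.05)
        assert len(ann.planted_multimap_probes) > 0
        flagged = flag_unspecific_probes(ann.probes, ann.genome)
        flagged_ids = set(flagged.loc[flagged["unspecific"], "probe_id"])
        planted = set(ann.planted_multimap_probes)
        assert len(planted & flagged_ids) / len(planted) > 0.9


class TestPlantTranscriptome:
    def test_reciprocal_pair_lists_both_directions(self):
        ann = generate_annotation(**SMALL, seed=1)
        ids = [g.gene_id for g in ann.genes]
        spec = NetworkSpec(samples=("s1", "s2"), reciprocal_pairs=((ids[0], ids[1]),))
        truth = plant_transcriptome(ann, spec, seed=0)
        assert set(truth.network) == {(ids[0], ids[1]), (ids[1], ids[0])}

    def test_four_clique_expands_to_six_pairs(self):
        ann = generate_annotation(n_chroms=1, chrom_len_nt=80_000, n_genes=8, seed=1)
        ids = [g.gene_id for g in ann.genes]
        spec = NetworkSpec(samples=("s1",), cliques=(tuple(ids[:4]),))
        truth = plant_transcriptome(ann, spec, seed=0)
        assert len(truth.reciprocal_pairs()) == 6
        assert len(truth.chimeras) == 12

    def test_overlapping_gene_edge_rejected(self):
        gene_a = GeneModel(
            "a", GenomicInterval("chr1", 0, 1_000, "+"),
            [[GenomicInterval("chr1", 0, 1_000, "+")]],
        )
        gene_b = GeneModel(
            "b", GenomicInterval("chr1", 500, 1_500, "-"),
            [[GenomicInterval("chr1", 500, 1_500, "-")]],
        )
        ann = SyntheticAnnotation({}, [gene_a, gene_b], [], pd.DataFrame())
        spec = NetworkSpec(samples=("s1",), reciprocal_pairs=((("a"), ("b")),))
        with pytest.raises(ConfigurationError, match="overlapping"):
            plant_transcriptome(ann, spec, seed=0)

    def test_hub_degree_planted(self):
        ann = generate_annotation(n_chroms=1, chrom_len_nt=120_000, n_genes=10, seed=2)
        hub = ann.genes[4].gene_id
        spec = NetworkSpec(samples=("s1",), hubs={hub: 4}, max_partner_gap=40_000)
        truth = plant_transcriptome(ann, spec, seed=0)
        assert sum(1 for p in truth.reciprocal_pairs() if hub in p) == 4


class TestArrayTracks:
    def _world(self, seed=1):
        ann = generate_annotation(**SMALL, seed=seed)
        ids = [g.gene_id for g in ann.genes]
        spec = NetworkSpec(samples=("s1", "s2"), reciprocal_pairs=((ids[0], ids[1]),))
        truth = plant_transcriptome(ann, spec, seed=seed)
        cfg = PoolingConfig(L=20_000, l=2_000)
        _, k = min_pool_count(ann.primers, cfg)
        pools = assign_pools(ann.primers, k, cfg)
        return ann, truth, pools

    def test_zero_amplitude_yields_no_calls(self):
        from racenet.calling import CallerParams, call_racefrags

        ann, truth, pools = self._world()
        noise = NoiseConfig(amplitude=0.0, xhyb_rate=0.0, n_abundant_per_sample=0)
        tracks, _ = simulate_array_tracks(truth, ann, pools, ("s1",), noise, seed=0)
        frags = [
            f for t in tracks.values()
            for f in call_racefrags(t, CallerParams())  # caller defaults
        ]
        assert frags == []  # background-only tracks yield nothing

    def test_seeded_run_reproducible(self):
        ann, truth, pools = self._world()
        t1, n1 = simulate_array_tracks(truth, ann, pools, ("s1",), NoiseConfig(), seed=9)
        t2, n2 = simulate_array_tracks(truth, ann, pools, ("s1",), NoiseConfig(), seed=9)
        for k in t1:
            pd.testing.assert_frame_equal(t1[k], t2[k])
        for s in n1:
            pd.testing.assert_frame_equal(n1[s], n2[s])

    def test_noise_free_positive_probes_match_overlap_oracle(self):
        """With zero noise, positive probes are exactly those overlapping
        the single primer's RACE product footprint."""
        gene = GeneModel(
            "g1", GenomicInterval("chr1", 1_000, 1_400, "+"),
            [[GenomicInterval("chr1", 1_000, 1_400, "+")]],
        )
        from racenet.pooling import PrimerPool, RacePrimer

        primer = RacePrimer("g1_3p", "g1", GenomicInterval("chr1", 1_100, 1_125, "+"), "3p")
        probes = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(200)],
                "chrom": "chr1",
                "start": [i * 17 for i in range(200)],
                "end": [i * 17 + 25 for i in range(200)],
            }
        )
        ann = SyntheticAnnotation({"chr1": "A" * 4_000}, [gene], [primer], probes)
        truth = simulate.TruthTable([], {}, {}, [], [])
        noise = NoiseConfig(bg_log_sd=1e-9, bg_log_mean=0.0, amplitude=10.0,
                            xhyb_rate=0.0, n_abundant_per_sample=0)
        tracks, _ = simulate_array_tracks(
            truth, ann, [PrimerPool("pool1", ["g1_3p"])], ("s1",), noise, seed=0,
            min_probe_overlap=8,
        )
        track = next(iter(tracks.values()))
        positive = track.loc[track["intensity"] > 5.0]
        product = GenomicInterval("chr1", 1_100, 1_400)  # priming site to 3' end
        expected = {
            row.probe_id
            for row in probes.itertuples()
            if min(row.end, product.end) - max(row.start, product.start) >= 8
        }
        assert set(positive["probe_id"]) == expected

    def test_negative_controls_contain_only_abundant_signal(self):
        ann, truth, pools = self._world()
        noise = NoiseConfig(n_abundant_per_sample=1, xhyb_rate=0.0)
        tracks, negs = simulate_array_tracks(truth, ann, pools, ("s1",), noise, seed=4)
        neg = negs["s1"]
        strong = neg.loc[neg["intensity"] > noise.amplitude / 2]
        # the abundant transcript spans ~1.2 kb: tens of probes, contiguous
        # up to a handful of background outliers
        assert 30 <= len(strong) <= 200
        spans = np.sort(strong["start"].to_numpy())
        lo, hi = np.percentile(spans, [5, 95])
        assert hi - lo <= 2 * noise.abundant_len


class TestAuxData:
    def _many_pair_truth(self, n_pairs=400):
        """Fake annotation with each connected pair on its own chromosome
        (keeps the 5C pair table small)."""
        genes, pairs = [], {}
        for i in range(n_pairs):
            chrom = f"c{i}"
            a = GeneModel(f"a{i}", GenomicInterval(chrom, 0, 1_000, "+"),
                          [[GenomicInterval(chrom, 0, 1_000, "+")]])
            b = GeneModel(f"b{i}", GenomicInterval(chrom, 2_000, 3_000, "+"),
                          [[GenomicInterval(chrom, 2_000, 3_000, "+")]])
            genes += [a, b]
            pairs[(f"a{i}", f"b{i}")] = {"s1"}
        ann = SyntheticAnnotation({}, genes, [], pd.DataFrame())
        truth = simulate.TruthTable([], {}, pairs, [], [])
        return ann, truth

    def test_connected_pair_correlation_hits_target(self):
        ann, truth = self._many_pair_truth(400)
        aux = simulate_aux_data(truth, ann, AuxConfig(n_expr_samples=16), seed=0)
        x = aux.expression
        rs = [
            float(np.corrcoef(x.loc[f"a{i}"], x.loc[f"b{i}"])[0, 1]) for i in range(400)
        ]
        assert np.mean(rs) == pytest.approx(0.2, abs=0.05)

    def test_baseline_correlation(self):
        ann, truth = self._many_pair_truth(200)
        aux = simulate_aux_data(truth, ann, AuxConfig(n_expr_samples=16), seed=1)
        x = aux.expression
        rs = [
            float(np.corrcoef(x.loc[f"a{i}"], x.loc[f"b{i+1}"])[0, 1]) for i in range(199)
        ]
        assert np.mean(rs) == pytest.approx(0.07, abs=0.05)

    def test_mixture_counts_scale_linearly_without_artifact(self):
        ann, truth = self._many_pair_truth(2)
        cfg = AuxConfig(human_bio_n1=100_000.0, human_art_a1=0.0, dilutions=(1, 5, 50))
        aux = simulate_aux_data(truth, ann, cfg, seed=2)
        mixes = {m.dilution: m for m in aux.mixtures if m.label.startswith("mix")}
        assert mixes[5].intra_human == pytest.approx(100_000 / 5, rel=0.05)
        assert mixes[50].intra_human == pytest.approx(100_000 / 50, rel=0.05)

    def test_no_enrichment_gives_background_validation_rate(self):
        ann = generate_annotation(n_chroms=1, chrom_len_nt=120_000, n_genes=12, seed=3)
        ids = [g.gene_id for g in ann.genes]
        spec = NetworkSpec(samples=("s1",), reciprocal_pairs=tuple(
            (ids[i], ids[i + 1]) for i in range(0, 10, 2)
        ))
        truth = plant_transcriptome(ann, spec, seed=3)
        cfg = AuxConfig(fivec_enrichment=0.0, q_top=10.0)
        aux = simulate_aux_data(truth, ann, cfg, seed=4)
        scores = np.array([p.score for p in aux.fivec])
        assert (scores >= np.percentile(scores, 90)).mean() == pytest.approx(0.1, abs=0.05)

    def test_invalid_target_correlation(self):
        with pytest.raises(ValueError):
            AuxConfig(r_connected=1.5)


class TestGenerateProducts:
    def _products(self, seed=2, dup_rate=0.5):
        ann = generate_annotation(n_chroms=2, chrom_len_nt=120_000, n_genes=16, seed=seed)
        ids = [g.gene_id for g in ann.genes]
        spec = NetworkSpec(
            samples=("s1",),
            reciprocal_pairs=tuple((ids[i], ids[i + 1]) for i in range(0, 12, 2)),
        )
        truth = plant_transcriptome(ann, spec, seed=seed)
        products = generate_products(truth, ann, DupConfig(dup_rate=dup_rate), seed=seed)
        return ann, truth, products

    def test_planted_duplication_lengths_recovered_exactly(self):
        ann, truth, products = self._products(dup_rate=1.0)
        assert products
        for i, prod in enumerate(products):
            length, flagged = junction_duplication(ann.genome, prod.blocks, min_len=5)
            assert length == prod.dup_length == truth.junction_duplications[i]
            assert flagged

    def test_planted_splice_classes_recovered(self):
        ann, _, products = self._products(dup_rate=0.0)
        assert products
        for prod in products:
            assert classify_splice_junction(ann.genome, prod.blocks) == prod.splice_class
            # splice-class products carry no junction duplication
            length, _ = junction_duplication(ann.genome, prod.blocks, min_len=5)
            assert length == 0 and prod.dup_length == 0

    def test_product_sequence_concatenates_blocks(self):
        ann, _, products = self._products()
        for prod in products:
            b = prod.blocks
            expected = (
                ann.genome[b.left.chrom][b.left.start : b.left.end]
                + ann.genome[b.right.chrom][b.right.start : b.right.end]
            )
            assert prod.sequence == expected

    def test_duplicated_kmer_once_in_product_twice_in_genome(self):
        ann, _, products = self._products(dup_rate=1.0)
        prod = products[0]
        k = prod.dup_length
        b = prod.blocks
        dup_seq = ann.genome[b.right.chrom][b.right.start : b.right.start + k]
        flank_after_left = ann.genome[b.left.chrom][b.left.end : b.left.end + k]
        assert dup_seq == flank_after_left  # flanks both junction sides
        assert prod.sequence.count(dup_seq) >= 1
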