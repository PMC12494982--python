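import numpy as np
import pytest

from tnseqmap.decay import (
    DecayProfile,
    GENE_AUC_PASSAGES,
    assign_auc,
    auc,
    build_trajectories,
    compare_libraries_auc,
    kmeans_decay,
    termini_analysis,
)
from tnseqmap.windows import Segment


def profile(values, passages=(1, 2, 3, 4, 6, 8, 10), fid="f"):
    return DecayProfile(fid, tuple(passages), np.asarray(values, dtype=float))


class TestAuc:
    def test_constant_one_equals_span(self):
        assert auc(profile(np.ones(7))) == pytest.approx(9.0, abs=1e-12)

    def test_two_point_triangle(self):
        assert auc(profile([1, 0], passages=(1, 2)), passage_range=(1, 2)) == pytest.approx(
            0.5, abs=1e-12
        )

    def test_linear_decay_closed_form(self):
        xs = np.array(GENE_AUC_PASSAGES, dtype=float)
        ys = (10 - xs) / 9
        # trapezoid on nodes of a linear function equals the exact integral:
        # area of a triangle with base 9 and height 1
        assert auc(profile(ys)) == pytest.approx(4.5, abs=1e-12)

    def test_restricted_range(self):
        p = profile(np.ones(7))
        assert auc(p, passage_range=(1, 2, 3, 4)) == pytest.approx(3.0, abs=1e-12)

    def test_too_few_points_in_range(self):
        p = profile([1, 1], passages=(1, 2))
        with pytest.raises(ValueError):
            auc(p, passage_range=(5, 6))

    def test_linearity_in_trajectory(self):
        rng = np.random.default_rng(0)
        y = rng.random(7)
        a = 3.7
        assert auc(profile(a * y)) == pytest.approx(a * auc(profile(y)), rel=1e-12)

    def test_flat_trajectory_value_times_span(self):
        assert auc(profile(np.full(7, 0.3))) == pytest.approx(0.3 * 9, abs=1e-12)


class TestBuildTrajectories:
    def test_gold_ne_tracks_one(self):
        ld = {
            p: {"g1": 0.9 * 0.97 ** (p - 1), "g2": 0.9 * 0.97 ** (p - 1), "e1": 0.0}
            for p in (1, 2, 3)
        }
        profs = {pr.feature_id: pr for pr in build_trajectories(ld, {"g1", "g2"})}
        np.testing.assert_allclose(profs["g1"].values, 1.0)
        np.testing.assert_allclose(profs["e1"].values, 0.0)

    def test_trajectory_length_matches_passages(self):
        ld = {p: {"a": 0.5, "g": 1.0} for p in (1, 2, 4, 8)}
        profs = build_trajectories(ld, {"g"})
        assert all(len(pr.passages) == 4 for pr in profs)

    def test_feature_missing_passages_skipped(self):
        ld = {1: {"a": 0.5, "g": 1.0}, 2: {"g": 1.0}, 3: {"g": 1.0}}
        profs = build_trajectories(ld, {"g"})
        ids = {pr.feature_id for pr in profs}
        assert "a" not in ids  # only 1 defined passage

    def test_needs_two_passages(self):
        with pytest.raises(ValueError):
            build_trajectories({1: {"a": 1.0}}, {"a"})


class TestKmeansDecay:
    def test_identical_trajectories_select_k1(self):
        profs = [profile(np.ones(7), fid=f"f{i}") for i in range(30)]
        res = kmeans_decay(profs, min_cluster_size=5, seed=0)
        assert res.k == 1
        assert res.distortion.loc[res.distortion["k"] == 1, "distortion"].iloc[0] == pytest.approx(0.0)

    def test_min_cluster_size_reduces_k(self):
        rng = np.random.default_rng(1)
        profs = [
            profile(rng.random(7) + (5 if i % 2 else 0), fid=f"f{i}") for i in range(20)
        ]
        res = kmeans_decay(profs, min_cluster_size=15, seed=0)
        assert res.k == 1  # no multi-cluster split can give clusters >= 15

    def test_fewer_profiles_than_k(self):
        profs = [profile(np.ones(7), fid=f"f{i}") for i in range(3)]
        with pytest.raises(ValueError):
            kmeans_decay(profs, k=5, seed=0)

    def test_high_repeat_features_excluded(self):
        profs = [profile(np.ones(7), fid=f"f{i}") for i in range(10)]
        pct = {"f0": 0.9}
        res = kmeans_decay(profs, pct_repeated=pct, min_cluster_size=2, seed=0)
        assert "f0" in res.excluded
        assert all(pr.feature_id != "f0" for pr in res.profiles)

    def test_labels_ordered_by_auc_and_stable(self):
        rng = np.random.default_rng(2)
        profs = [profile(np.full(7, 0.05) + rng.normal(0, 0.01, 7), fid=f"lo{i}") for i in range(20)]
        profs += [profile(np.full(7, 1.0) + rng.normal(0, 0.01, 7), fid=f"hi{i}") for i in range(20)]
        res1 = kmeans_decay(list(profs), k=2, min_cluster_size=5, seed=0)
        labels1 = {pr.feature_id: pr.cluster for pr in res1.profiles}
        assert all(labels1[f"lo{i}"] == 0 for i in range(20))
        assert all(labels1[f"hi{i}"] == 1 for i in range(20))
        res2 = kmeans_decay(list(profs), k=2, min_cluster_size=5, seed=0)
        assert labels1 == {pr.feature_id: pr.cluster for pr in res2.profiles}


class TestCompareLibraries:
    def _reps(self, values, fid="x"):
        return [profile(values, fid=fid), profile(np.asarray(values) * 1.001, fid=fid)]

    def test_identical_is_ns(self):
        p = {"x": self._reps(np.ones(7))}
        t = {"x": self._reps(np.ones(7))}
        (res,) = compare_libraries_auc(p, t)
        assert res.verdict == "n.s."
        assert res.fold_change == pytest.approx(1.0, abs=0.01)

    def test_swap_inverts_fold_change(self):
        rng = np.random.default_rng(3)
        a = {"x": [profile(np.full(7, 2.0) + rng.normal(0, 0.05, 7)) for _ in range(3)]}
        b = {"x": [profile(np.full(7, 1.0) + rng.normal(0, 0.05, 7)) for _ in range(3)]}
        (fwd,) = compare_libraries_auc(a, b)
        (rev,) = compare_libraries_auc(b, a)
        assert fwd.fold_change == pytest.approx(1 / rev.fold_change, rel=1e-9)

    def test_clear_separation_is_significant(self):
        rng = np.random.default_rng(4)
        p = {"x": [profile(np.full(7, 3.0) + rng.normal(0, 0.01, 7)) for _ in range(4)]}
        t = {"x": [profile(np.full(7, 0.5) + rng.normal(0, 0.01, 7)) for _ in range(4)]}
        (res,) = compare_libraries_auc(p, t)
        assert res.verdict == "P-enriched"
        assert res.p_value < 0.05

    def test_simulated_p_bias_upstream_of_e_genes(self):
        # P-library insertions upstream of E genes decay more slowly than in
        # the T library; AUC comparisons should call those elements P-enriched
        # more often than elements elsewhere.
        from tnseqmap.genome import compute_repeat_mask, upstream_interval
        from tnseqmap.metrics import metrics_table
        from tnseqmap.simulate import (
            SimConfig,
            generate_annotation,
            generate_genome,
            simulate_library,
        )

        cfg = SimConfig(
            genome_length=60_000,
            n_genes=60,
            decay_rate={"E": 0.05, "F1": 0.3, "F2": 0.6, "NE": 0.7},
            p_regulatory_bias=1.0,
            upstream_bias_window=200,
            seed=23,
        )
        genome, _ = generate_genome(cfg)
        annot = generate_annotation(cfg, genome)
        mask = compute_repeat_mask(genome)
        gold = {f.id for f in annot if f.gold_ne}
        passages = (1, 2, 3, 4, 6, 8)
        elements = annot.of_type("iGiO", "UTR5", "promoter", "UTR3", "TTS")

        def replicate_profiles(library):
            out = {el.id: [] for el in elements}
            for rep in (1, 2):
                ld_by_passage = {}
                for p in passages:
                    (sample,) = [
                        s
                        for s in simulate_library(cfg, genome, annot, library, [p], 2)
                        if s.replicate == rep
                    ]
                    table = metrics_table(sample, annot, mask=mask)
                    ld_by_passage[p] = table["ld"].dropna().to_dict()
                profs = build_trajectories(ld_by_passage, gold)
                by_id = {pr.feature_id: pr for pr in profs}
                for el in elements:
                    if el.id in by_id:
                        out[el.id].append(by_id[el.id])
            return {k: v for k, v in out.items() if len(v) == 2}

        res = compare_libraries_auc(
            replicate_profiles("P"), replicate_profiles("T"), passage_range=passages
        )
        biased_ids = set()
        e_genes = [f for f in annot.genes if f.true_class == "E"]
        for el in elements:
            for g in e_genes:
                us, ue = upstream_interval(g, cfg.upstream_bias_window, genome.length)
                if ue >= us and el.overlaps(us, ue):
                    biased_ids.add(el.id)
        in_bias = [r for r in res if r.element_id in biased_ids]
        outside = [r for r in res if r.element_id not in biased_ids]
        frac = lambda rs: np.mean([r.verdict == "P-enriched" for r in rs]) if rs else 0.0
        assert frac(in_bias) > frac(outside)


class TestTerminiAnalysis:
    def test_ne_head_segment_gives_aa_extension(self):
        from tnseqmap.genome import Feature

        g = Feature("g", "gene", 100, 400, "+")
        segs = [Segment(1, 114, "NE"), Segment(115, 500, "E")]
        (res,) = termini_analysis([g], segs)
        assert res.n_extension_aa == 5  # 15 bp overlap -> 5 aa
        assert res.c_extension_aa == 0

    def test_fully_ne_gene_capped_by_length(self):
        from tnseqmap.genome import Feature

        g = Feature("g", "gene", 100, 399, "+")
        segs = [Segment(1, 500, "NE")]
        (res,) = termini_analysis([g], segs)
        assert res.n_extension_aa == 100
        assert res.c_extension_aa == 100

    def test_fully_e_gene_zero_extension(self):
        from tnseqmap.genome import Feature

        g = Feature("g", "gene", 100, 400, "+")
        segs = [Segment(1, 500, "E")]
        (res,) = termini_analysis([g], segs)
        assert res.n_extension_aa == 0 and res.c_extension_aa == 0

    def test_minus_strand_swaps_termini(self):
        from tnseqmap.genome import Feature

        g = Feature("g", "gene", 100, 400, "-")
        segs = [Segment(1, 114, "NE"), Segment(115, 500, "E")]
        (res,) = termini_analysis([g], segs)
        assert res.c_extension_aa == 5 and res.n_extension_aa == 0

    def test_simulated_e_termini_extension(self):
        # generator parameters: termini_frac=0.02 of ~1500 bp genes -> 30 bp
        # fully-insertable termini -> ~10 aa recovered extensions
        from tnseqmap.genome import compute_repeat_mask
        from tnseqmap.insertions import merge_samples
        from tnseqmap.simulate import (
            SimConfig,
            generate_annotation,
            generate_genome,
            simulate_library,
        )
        from tnseqmap.windows import segment_genome

        cfg = SimConfig(
            genome_length=90_000,
            n_genes=50,
            termini_frac=0.02,
            density_p1={"E": 0.92, "F1": 0.15, "F2": 0.45, "NE": 0.92},
            seed=17,
        )
        g, _ = generate_genome(cfg)
        annot = generate_annotation(cfg, g)
        merged = merge_samples(
            simulate_library(cfg, g, annot, "P", [1], 2)
            + simulate_library(cfg, g, annot, "T", [1], 2),
            trim=0.05,
        )
        segs = segment_genome(merged, g, mask=compute_repeat_mask(g), seed=0)
        e_genes = [f for f in annot.genes if f.true_class == "E"]
        res = termini_analysis(e_genes, segs)
        mean_n = np.mean([r.n_extension_aa for r in res])
        # gene length ~1530 bp -> termini ~31 bp -> ~10 aa
        assert 5 <= mean_n <= 16


class TestAucOrderingOnSimulation:
    def test_mean_auc_strictly_ordered_by_class(self, small_world):
        from conftest import simulate_ld_by_passage

        cfg, genome, annot, mask, _ = small_world
        ld = simulate_ld_by_passage(cfg, genome, annot, mask)
        gold = {f.id for f in annot if f.gold_ne}
        profs = build_trajectories(ld, gold)
        assign_auc(profs)
        true = {f.id: f.true_class for f in annot.genes}
        by_class = {c: [] for c in ("E", "F1", "F2", "NE")}
        for pr in profs:
            by_class[true[pr.feature_id]].append(pr.auc)
        means = {c: np.mean(v) for c, v in by_class.items()}
        assert means["E"] < means["F1"] < means["F2"] < means["NE"]
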