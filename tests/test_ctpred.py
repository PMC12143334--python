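import numpy as np
import pytest
from scipy.stats import pearsonr, rankdata

from sctwas.ctpred import (ChromosomeSplit, CtPredHyperparams, CtPredModel,
                           evaluate_across_genes, evaluate_across_individuals,
                           load_model, parameter_count, predict, save_model,
                           split_by_chromosome, train_ctpred)
from sctwas.epifeatures import GeneAnnotation
from sctwas.simulate import FULL_N_TRACKS


def linear_fixture(n_genes=400, d=53, n_chroms=10, seed=0):
    """Noise-free linear feature -> percentile map over synthetic genes."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_genes, d))
    u = rng.standard_normal(d)
    pct = (rankdata(X @ u) - 1) / (n_genes - 1)
    genes = [GeneAnnotation(f"G{i:04d}", f"chr{i % n_chroms + 1}", 1000 + i)
             for i in range(n_genes)]
    feats = {g.gene_id: X[i] for i, g in enumerate(genes)}
    targets = {g.gene_id: pct[i] for i, g in enumerate(genes)}
    return genes, feats, targets


class TestArchitecture:
    def test_full_profile_parameter_count(self):
        assert parameter_count(FULL_N_TRACKS) == 352_641

    def test_instantiated_model_parameter_count(self):
        from sctwas.ctpred import _init_model
        model = _init_model(FULL_N_TRACKS, CtPredHyperparams(),
                            "ct", np.random.default_rng(0))
        assert model.n_parameters() == 352_641
        assert round(model.n_parameters() / 1e6, 1) == 0.4

    def test_hyperparam_validation(self):
        with pytest.raises(ValueError, match="dropout"):
            CtPredHyperparams(dropout=1.0)
        with pytest.raises(ValueError, match="weight_decay"):
            CtPredHyperparams(weight_decay=-1)


class TestPredict:
    def build_toy(self, W, b):
        return CtPredModel(weights=[np.asarray(w, dtype=float) for w in W],
                           biases=[np.asarray(x, dtype=float) for x in b],
                           hyperparams=CtPredHyperparams())

    def test_zero_weights_output_final_bias(self):
        model = self.build_toy(
            [np.zeros((2, 3)), np.zeros((3, 3)), np.zeros((3, 1))],
            [np.zeros(3), np.zeros(3), np.array([0.7])])
        out = predict(model, np.array([[1.0, -2.0], [5.0, 5.0]]))
        np.testing.assert_allclose(out, 0.7)

    def test_hand_computed_forward_pass(self):
        # 2 features -> 2 hidden (ReLU) -> 1 output, arithmetic by hand
        model = self.build_toy(
            [np.array([[1.0, 0.0], [0.0, -1.0]]), np.array([[2.0], [1.0]])],
            [np.array([0.0, 0.5]), np.array([0.25])])
        x = np.array([3.0, -1.0])
        # layer 1: a = (3, 1.5) -> relu unchanged; out = 2*3 + 1*1.5 + 0.25
        np.testing.assert_allclose(predict(model, x[None, :]), [7.75])
        x2 = np.array([-3.0, 1.0])
        # layer 1: a = (-3, -0.5) -> relu (0, 0); out = 0.25
        np.testing.assert_allclose(predict(model, x2[None, :]), [0.25])

    def test_determinism_and_order_invariance(self):
        genes, feats, targets = linear_fixture(60, d=8, n_chroms=5, seed=1)
        split = split_by_chromosome(genes, seed=1)
        model, _ = train_ctpred(feats, targets, split, genes,
                                CtPredHyperparams(seed=0, max_epochs=5))
        X = np.vstack([feats[g.gene_id] for g in genes])
        a = predict(model, X)
        b = predict(model, X[::-1])[::-1]
        np.testing.assert_allclose(a, b)
        np.testing.assert_allclose(a, predict(model, X))

    def test_dimension_mismatch(self):
        model = self.build_toy([np.zeros((4, 2)), np.zeros((2, 1))],
                               [np.zeros(2), np.zeros(1)])
        with pytest.raises(ValueError, match="feature dim"):
            predict(model, np.zeros((1, 3)))


class TestSplit:
    def make_genes(self, counts):
        genes = []
        k = 0
        for chrom, n in counts.items():
            for _ in range(n):
                genes.append(GeneAnnotation(f"G{k:04d}", chrom, 1000 + k))
                k += 1
        return genes

    def test_three_chromosomes_one_each(self):
        genes = self.make_genes({"chr1": 5, "chr2": 5, "chr3": 5})
        split = split_by_chromosome(genes, (1 / 3, 1 / 3, 1 / 3), seed=0)
        assert len(split.train) == len(split.validation) == len(split.test) == 1

    def test_disjoint_gene_sets(self):
        genes = self.make_genes({f"chr{i}": i + 1 for i in range(1, 9)})
        split = split_by_chromosome(genes, seed=3)
        assert not (split.train & split.test)
        assert not (split.train & split.validation)
        union = split.train | split.validation | split.test
        assert union == {f"chr{i}" for i in range(1, 9)}

    def test_matches_brute_force_greedy_rule(self):
        counts = {f"chr{i}": (i * 7) % 11 + 1 for i in range(1, 23)}
        genes = self.make_genes(counts)
        fractions = (0.7, 0.15, 0.15)
        split = split_by_chromosome(genes, fractions, seed=5)
        # independent re-run of the documented rule
        rng = np.random.default_rng(5)
        order = list(rng.permutation(sorted(counts)))
        total = sum(counts.values())
        targets = [f * total for f in fractions]
        sizes = [0.0, 0.0, 0.0]
        sets = [set(), set(), set()]
        for c in order:
            k = int(np.argmax([targets[i] - sizes[i] for i in range(3)]))
            sets[k].add(c)
            sizes[k] += counts[c]
        assert (split.train, split.validation, split.test) == tuple(map(frozenset, sets))

    def test_too_few_chromosomes(self):
        genes = self.make_genes({"chr1": 3, "chr2": 3})
        with pytest.raises(ValueError, match="3 chromosomes"):
            split_by_chromosome(genes)

    def test_bad_fractions(self):
        genes = self.make_genes({"chr1": 1, "chr2": 1, "chr3": 1})
        with pytest.raises(ValueError, match="sum to 1"):
            split_by_chromosome(genes, (0.5, 0.5, 0.5))

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            ChromosomeSplit(frozenset({"chr1"}), frozenset({"chr1"}),
                            frozenset({"chr2"}))


class TestTraining:
    def test_constant_target_learned(self):
        genes, feats, _ = linear_fixture(80, d=6, n_chroms=5, seed=2)
        targets = {g.gene_id: 0.5 for g in genes}
        split = split_by_chromosome(genes, seed=2)
        model, log = train_ctpred(feats, targets, split, genes,
                                  CtPredHyperparams(seed=0, max_epochs=150,
                                                    dropout=0.0, patience=40,
                                                    learning_rate=0.03,
                                                    batch_size=16))
        assert log["val_mse"].min() < 1e-3

    def test_linear_map_recovery(self):
        genes, feats, targets = linear_fixture(400, d=53, seed=0)
        split = split_by_chromosome(genes, seed=1)
        model, _ = train_ctpred(feats, targets, split, genes,
                                CtPredHyperparams(seed=0, max_epochs=200,
                                                  patience=25))
        test = [g.gene_id for g in genes if g.chromosome in split.test]
        r, _, _ = evaluate_across_genes(
            predict(model, np.vstack([feats[g] for g in test])),
            np.array([targets[g] for g in test]))
        assert r >= 0.9

    def test_shuffled_targets_give_null_correlation(self):
        genes, feats, targets = linear_fixture(400, d=53, seed=0)
        rng = np.random.default_rng(7)
        vals = rng.permutation(list(targets.values()))
        shuffled = dict(zip(targets.keys(), vals))
        split = split_by_chromosome(genes, seed=1)
        model, _ = train_ctpred(feats, shuffled, split, genes,
                                CtPredHyperparams(seed=0, max_epochs=80))
        test = [g.gene_id for g in genes if g.chromosome in split.test]
        r, _, _ = evaluate_across_genes(
            predict(model, np.vstack([feats[g] for g in test])),
            np.array([shuffled[g] for g in test]))
        assert abs(r) < 0.1

    def test_missing_features_error(self):
        genes, feats, targets = linear_fixture(30, d=4, n_chroms=5, seed=3)
        feats.pop(genes[0].gene_id)
        split = split_by_chromosome(genes, seed=1)
        with pytest.raises(KeyError, match=genes[0].gene_id):
            train_ctpred(feats, targets, split, genes, CtPredHyperparams(max_epochs=2))

    def test_large_weight_decay_shrinks_weights(self):
        genes, feats, targets = linear_fixture(80, d=6, n_chroms=5, seed=4)
        split = split_by_chromosome(genes, seed=1)
        small_wd, _ = train_ctpred(feats, targets, split, genes,
                                   CtPredHyperparams(seed=0, max_epochs=40,
                                                     weight_decay=5e-4))
        big_wd, _ = train_ctpred(feats, targets, split, genes,
                                 CtPredHyperparams(seed=0, max_epochs=40,
                                                   weight_decay=50.0))
        norm = lambda m: sum(float(np.abs(w).sum()) for w in m.weights)
        assert norm(big_wd) < 0.3 * norm(small_wd)

    def test_reproducible_losses(self):
        genes, feats, targets = linear_fixture(60, d=6, n_chroms=5, seed=5)
        split = split_by_chromosome(genes, seed=1)
        hp = CtPredHyperparams(seed=9, max_epochs=10)
        _, log1 = train_ctpred(feats, targets, split, genes, hp)
        _, log2 = train_ctpred(feats, targets, split, genes, hp)
        np.testing.assert_array_equal(log1["val_mse"], log2["val_mse"])


class TestEvaluation:
    def test_identity_gives_one(self):
        x = np.linspace(0, 1, 20)
        r, p, n = evaluate_across_genes(x, x)
        assert r == pytest.approx(1.0)

    def test_antitone_gives_minus_one(self):
        x = np.linspace(0, 1, 20)
        r, _, _ = evaluate_across_genes(x, -x + 1)
        assert r == pytest.approx(-1.0)

    def test_textbook_formula(self):
        rng = np.random.default_rng(8)
        a, b = rng.random(50), rng.random(50)
        r, _, _ = evaluate_across_genes(a, b)
        am, bm = a - a.mean(), b - b.mean()
        manual = (am * bm).sum() / np.sqrt((am**2).sum() * (bm**2).sum())
        assert r == pytest.approx(manual)

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        a, b = rng.random(30), rng.random(30)
        r1, _, _ = evaluate_across_genes(a, b)
        r2, _, _ = evaluate_across_genes(3.0 * a - 1.0, b)
        assert r1 == pytest.approx(r2)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="variance"):
            evaluate_across_genes(np.ones(10), np.arange(10.0))

    def test_too_few_genes(self):
        with pytest.raises(ValueError, match=">= 3"):
            evaluate_across_genes(np.ones(2), np.ones(2))


class TestAcrossIndividuals:
    def frame(self, arr, genes=None):
        import pandas as pd
        genes = genes or [f"G{i}" for i in range(arr.shape[0])]
        return pd.DataFrame(arr, index=genes,
                            columns=[f"I{j}" for j in range(arr.shape[1])])

    def test_null_gives_uniform_p_and_small_pi1(self):
        rng = np.random.default_rng(10)
        pred = self.frame(rng.standard_normal((300, 30)))
        obs = self.frame(rng.standard_normal((300, 30)))
        df, est = evaluate_across_individuals(pred, obs)
        assert est.pi1 < 0.1
        # p-value histogram close to uniform
        assert abs((df["pvalue"] < 0.5).mean() - 0.5) < 0.1

    def test_perfect_signal(self):
        rng = np.random.default_rng(11)
        base = rng.standard_normal((100, 30))
        pred = self.frame(base)
        obs = self.frame(base + 0.01 * rng.standard_normal((100, 30)))
        df, est = evaluate_across_individuals(pred, obs)
        assert (df["pvalue"] < 1e-6).all()
        assert est.m1 == pytest.approx(100, abs=2)

    def test_mixture_recovers_m1(self):
        rng = np.random.default_rng(12)
        n_true, n_null, n_ind = 50, 150, 40
        base = rng.standard_normal((n_true, n_ind))
        pred = np.vstack([base, rng.standard_normal((n_null, n_ind))])
        obs = np.vstack([base + 0.4 * rng.standard_normal((n_true, n_ind)),
                         rng.standard_normal((n_null, n_ind))])
        df, est = evaluate_across_individuals(self.frame(pred), self.frame(obs))
        assert est.m1 == pytest.approx(n_true, abs=20)

    def test_constant_rows_skipped(self):
        rng = np.random.default_rng(13)
        pred = rng.standard_normal((60, 10))
        obs = rng.standard_normal((60, 10))
        obs[5] = 1.0
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df, _ = evaluate_across_individuals(self.frame(pred), self.frame(obs))
        assert df.attrs["n_skipped"] == 1
        assert len(df) == 59

    def test_too_few_individuals(self):
        rng = np.random.default_rng(14)
        with pytest.raises(ValueError, match="individuals"):
            evaluate_across_individuals(self.frame(rng.random((5, 3))),
                                        self.frame(rng.random((5, 3))))


class TestSerialization:
    def test_round_trip(self, tmp_path):
        genes, feats, targets = linear_fixture(60, d=6, n_chroms=5, seed=6)
        split = split_by_chromosome(genes, seed=1)
        model, _ = train_ctpred(feats, targets, split, genes,
                                CtPredHyperparams(seed=0, max_epochs=5),
                                cell_type="CTx")
        path = tmp_path / "m.npz"
        save_model(model, path)
        back = load_model(path)
        assert back.cell_type == "CTx"
        assert back.train_chromosomes == model.train_chromosomes
        X = np.vstack([feats[g.gene_id] for g in genes[:10]])
        np.testing.assert_array_equal(predict(back, X), predict(model, X))
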