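import collections

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from zgene import classifier as clf
from zgene import gene_caller, orf_model, synthetic, zcurve
from zgene.sequence_io import ZgeneError

from conftest import orf_stop_key, truth_stop_keys


def toy_sets(n=20, d=5, sep=1.0, noise=0.05, seed=0):
    rng = np.random.default_rng(seed)
    pos = rng.normal(0, noise, size=(n, d))
    neg = rng.normal(0, noise, size=(n, d))
    pos[:, 0] += sep
    neg[:, 0] -= sep
    return clf.TrainingSets(positives=pos, negatives=neg)


class TestTrain:
    def test_separable_toy_classified_correctly(self):
        sets = toy_sets()
        model = clf.train(sets, seed=0)
        assert all(clf.score(model, v) > 0 for v in sets.positives)
        assert all(clf.score(model, v) < 0 for v in sets.negatives)

    def test_label_swap_negates_weights(self):
        sets = toy_sets()
        m1 = clf.train(sets, seed=0)
        m2 = clf.train(
            clf.TrainingSets(positives=sets.negatives, negatives=sets.positives),
            seed=0,
        )
        assert np.allclose(m1.weights, -m2.weights, atol=1e-3)
        assert m1.bias == pytest.approx(-m2.bias, abs=1e-3)

    def test_duplication_leaves_decision_stable(self):
        sets = toy_sets()
        m1 = clf.train(sets, seed=0)
        dup = clf.TrainingSets(
            positives=np.vstack([sets.positives, sets.positives]),
            negatives=np.vstack([sets.negatives, sets.negatives]),
        )
        m2 = clf.train(dup, seed=0)
        test = np.random.default_rng(1).normal(size=(50, 5))
        s1 = np.sign(clf.score_matrix(m1, test))
        s2 = np.sign(clf.score_matrix(m2, test))
        assert np.mean(s1 == s2) >= 0.95

    def test_empty_class_rejected(self):
        with pytest.raises(ZgeneError):
            clf.train(clf.TrainingSets(positives=np.empty((0, 3)),
                                       negatives=np.ones((2, 3))))

    def test_degenerate_constant_features_rejected(self):
        sets = clf.TrainingSets(positives=np.ones((5, 3)), negatives=np.ones((5, 3)))
        with pytest.raises(ZgeneError, match="degenerate"):
            clf.train(sets)


class TestScore:
    def test_zero_vector_gives_bias(self):
        m = clf.LinearModel(weights=np.array([1.0, 2.0]), bias=0.5)
        assert clf.score(m, np.zeros(2)) == 0.5

    def test_linearity(self):
        m = clf.LinearModel(weights=np.array([1.0, -1.0]), bias=0.25)
        u, v = np.array([0.2, 0.3]), np.array([-0.4, 0.1])
        assert clf.score(m, u + v) == pytest.approx(
            clf.score(m, u) + clf.score(m, v) - m.bias
        )

    def test_dimension_mismatch(self):
        m = clf.LinearModel(weights=np.ones(3), bias=0.0)
        with pytest.raises(ZgeneError):
            clf.score(m, np.ones(4))

    def test_serialization_round_trip_is_bitwise(self, tmp_path):
        rng = np.random.default_rng(0)
        m = clf.LinearModel(
            weights=rng.normal(size=765), bias=float(rng.normal()),
            threshold=0.3,
            calibration=clf.NullCalibration(mu_coef=(0.1, -2.0), sd_coef=(0.2, 3.0)),
        )
        p = tmp_path / "model.json"
        m.save(p)
        m2 = clf.LinearModel.load(p)
        v = rng.normal(size=765)
        assert clf.score(m, v) == clf.score(m2, v)
        assert m2.calibration.z(1.0, 300) == m.calibration.z(1.0, 300)


class TestBuildTrainingSets:
    def test_shuffle_preserves_composition(self):
        rng = np.random.default_rng(0)
        seq = "ATGGCTAAACCCGGGTTTTAA"
        sh = clf.shuffle_sequence(seq, rng)
        assert collections.Counter(sh) == collections.Counter(seq)
        assert sh[-3:] == seq[-3:]
        assert len(sh) == len(seq)

    def test_planted_long_genes_become_positives(self):
        spec = synthetic.SyntheticGenomeSpec(
            length=150_000, n_genes=100, gene_len_min=600, gene_len_mean=900,
            seed=11,
        )
        g = synthetic.generate_genome(spec)
        orfs = orf_model.extract_orfs(g.genome)
        sets = clf.build_training_sets(orfs, seed=11)
        assert len(sets.positives) >= 80
        assert set(sets.positive_tags) == {"long_orf"}
        tk = truth_stop_keys(g.truth)
        hits = sum(orf_stop_key(o) in tk for o in sets.positive_orfs)
        assert hits >= 0.8 * len(sets.positive_orfs)

    def test_provenance_tags_cover_policy(self, training_sets_main):
        tags = set(training_sets_main.negative_tags)
        assert tags == {"shuffled", "shadow"}
        assert len(training_sets_main.provenance) == len(
            training_sets_main.positives
        ) + len(training_sets_main.negatives)

    def test_pure_random_genome_has_too_few_positives(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=50_000))
        from zgene.sequence_io import GenomeSequence

        orfs = orf_model.extract_orfs(GenomeSequence(id="r", seq=seq))
        with pytest.raises(ZgeneError, match="seed positives"):
            clf.build_training_sets(orfs, seed=5)


class TestOnSyntheticGenome:
    def test_holdout_auc_high_with_codon_bias(self, training_sets_main):
        sets = training_sets_main
        rng = np.random.default_rng(0)
        n_pos, n_neg = len(sets.positives), len(sets.negatives)
        pi, ni = rng.permutation(n_pos), rng.permutation(n_neg)
        cut_p, cut_n = int(0.7 * n_pos), int(0.7 * n_neg)
        model = clf.train(
            clf.TrainingSets(
                positives=sets.positives[pi[:cut_p]],
                negatives=sets.negatives[ni[:cut_n]],
            ),
            seed=0,
        )
        scores = np.concatenate([
            clf.score_matrix(model, sets.positives[pi[cut_p:]]),
            clf.score_matrix(model, sets.negatives[ni[cut_n:]]),
        ])
        y = np.concatenate([
            np.ones(n_pos - cut_p), np.zeros(n_neg - cut_n),
        ])
        assert roc_auc_score(y, scores) >= 0.95

    def test_legacy_encoding_not_materially_better(self, pipeline_main):
        """The 765-variable encoding should not be materially worse than
        the legacy 33-variable one on held-out planted genes."""
        g = pipeline_main["synth"]
        orfs = pipeline_main["orfs"]
        tk = truth_stop_keys(g.truth)
        y = np.array([orf_stop_key(o) in tk for o in orfs])

        def auc_for(legacy):
            cfg = gene_caller.CallerConfig(seed=1, legacy=legacy)
            enc = (
                pipeline_main["encodings"]
                if not legacy
                else zcurve.encode_many([o.seq for o in orfs], legacy=True)
            )
            model = gene_caller.train_model([g.genome], cfg, orfs=orfs, encodings=enc)
            z = clf.calibrated_scores(model, enc, [o.length for o in orfs])
            return roc_auc_score(y, z)

        assert auc_for(legacy=True) <= auc_for(legacy=False) + 0.02


class TestRetrainIteration:
    def test_zero_iterations_is_identity(self, pipeline_main):
        m = pipeline_main["model"]
        out = clf.retrain_iteration(m, pipeline_main["encodings"], iterations=0)
        assert out is m

    def test_infinite_margin_warns_and_keeps_model(self, pipeline_main):
        m = pipeline_main["model"]
        with pytest.warns(UserWarning, match="single class"):
            out = clf.retrain_iteration(
                m, pipeline_main["encodings"], confidence_margin=np.inf
            )
        assert out is m

    def test_iteration_does_not_degrade_auc(self, pipeline_main, training_sets_main):
        g = pipeline_main["synth"]
        orfs = pipeline_main["orfs"]
        enc = pipeline_main["encodings"]
        tk = truth_stop_keys(g.truth)
        y = np.array([orf_stop_key(o) in tk for o in orfs])
        base = clf.train(training_sets_main, seed=1)
        refined = clf.retrain_iteration(base, enc, iterations=1, seed=1)
        auc0 = roc_auc_score(y, clf.score_matrix(base, enc))
        auc1 = roc_auc_score(y, clf.score_matrix(refined, enc))
        assert auc1 >= auc0 - 0.01
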