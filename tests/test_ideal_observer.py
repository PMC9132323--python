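"""Dirichlet-multinomial ideal observer: arithmetic, invariants, oracle."""

import math

import numpy as np
import pytest

from shapebias import features, ideal_observer as io, stimuli
from shapebias.features import extract, schema_for
from shapebias.stimuli import StimulusError

ALL_DATASETS = [
    ("exp1", "a"), ("exp1", "b"), ("exp2", "a"), ("exp2", "b"),
    ("exp3", "a"), ("exp3", "b"), ("exp4", "a"), ("exp4", "b"),
    ("exp5_patch", "noshape"), ("exp5_segment", "noshape"),
    ("exp5_size", "noshape"), ("exp5_colour", "noshape"),
]


def _fit_small(small_manifests, experiment, variant, n_train=100, n_test=20):
    man = small_manifests(experiment, variant, n_train=n_train, n_test=n_test)
    model = io.init_model(schema_for(experiment))
    io.fit(model, man.train_rows)
    return man, model


# --------------------------------------------------------------------------
# basic arithmetic
# --------------------------------------------------------------------------


class TestBasics:
    def test_untrained_posterior_is_uniform(self):
        model = io.init_model(schema_for("exp3"))
        rng = np.random.default_rng(0)
        spec = stimuli.sample_test_spec("exp3", "both", 3, rng)
        post = io.posterior(model, extract(spec))
        assert np.allclose(post.probabilities, 0.2, atol=1e-12)

    def test_degenerate_class_prior_dominates(self):
        model = io.init_model(schema_for("exp3"), class_prior=[1, 0, 0, 0, 0])
        rng = np.random.default_rng(0)
        spec = stimuli.sample_test_spec("exp3", "both", 3, rng)
        post = io.posterior(model, extract(spec))
        assert np.allclose(post.probabilities, [1, 0, 0, 0, 0])

    def test_init_is_reproducible(self):
        a = io.init_model(schema_for("exp2"))
        b = io.init_model(schema_for("exp2"))
        assert all(np.array_equal(x, y)
                   for x, y in zip(a.cat_counts, b.cat_counts))
        assert np.array_equal(a.block_counts, b.block_counts)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(StimulusError):
            io.init_model(schema_for("exp3"), alpha=0.0)

    def test_single_update_laplace_arithmetic(self):
        # one observation of value k on a K=6 channel: (1+1)/(1+6)
        model = io.init_model(schema_for("exp3"))
        rng = np.random.default_rng(0)
        spec = stimuli.sample_test_spec("exp3", "both", 2, rng)
        io.update(model, extract(spec), 2)
        assert io.class_conditional(model, "size", 2, 2) == pytest.approx(2 / 7)
        # untouched class is still flat
        assert io.class_conditional(model, "size", 2, 1) == pytest.approx(1 / 6)

    def test_heavily_trained_channel(self):
        model = io.init_model(schema_for("exp3"))
        rng = np.random.default_rng(0)
        spec = stimuli.sample_test_spec("exp3", "both", 1, rng)
        fv = extract(spec)
        for _ in range(400):
            io.update(model, fv, 1)
        assert io.class_conditional(model, "size", fv.values[1], 1) == \
            pytest.approx(401 / 406)

    def test_update_batch_order_irrelevant(self, small_manifests):
        man = small_manifests("exp2", "b")
        rows = man.train_rows
        a = io.fit(io.init_model(schema_for("exp2")), rows)
        shuffled = list(rows)
        np.random.default_rng(1).shuffle(shuffled)
        b = io.fit(io.init_model(schema_for("exp2")), shuffled)
        assert all(np.array_equal(x, y) for x, y in zip(a.cat_counts, b.cat_counts))
        assert np.array_equal(a.block_counts, b.block_counts)

    def test_class_conditionals_sum_to_one(self, small_manifests):
        _, model = _fit_small(small_manifests, "exp2", "a")
        for channel in range(model.schema.n_channels):
            ch = model.schema.channels[channel]
            for c in range(1, 6):
                total = sum(io.class_conditional(model, channel, k, c)
                            for k in range(ch.lo, ch.hi + 1))
                assert total == pytest.approx(1.0, abs=1e-10)

    def test_posterior_normalised(self, small_manifests):
        man, model = _fit_small(small_manifests, "exp1", "b")
        for spec in man.rows[:50]:
            p = io.posterior(model, extract(spec)).probabilities
            assert abs(p.sum() - 1.0) < 1e-12
            assert (p >= 0).all()


# --------------------------------------------------------------------------
# independent brute-force oracle
# --------------------------------------------------------------------------


def _oracle_posterior(schema, trials, test_fv, alpha=1.0):
    """Recompute the posterior by direct enumeration over the raw trial log,
    sharing no code with the model implementation (math.lgamma, pure python).
    """
    log_post = [math.log(0.2)] * 5
    cat_idx = schema.categorical_indices()
    for c in range(1, 6):
        rows = [fv for fv, lab in trials if lab == c]
        for j in cat_idx:
            ch = schema.channels[j]
            n_k = sum(fv.values[j] == test_fv.values[j] for fv in rows)
            log_post[c - 1] += math.log(
                (n_k + alpha) / (len(rows) + ch.cardinality * alpha))
        if schema.count_block is not None:
            lo, hi = schema.count_block
            K = hi - lo
            a = [alpha + sum(fv.values[j] for fv in rows)
                 for j in range(lo, hi)]
            x = list(test_fv.values[lo:hi])
            n = sum(x)
            log_post[c - 1] += (
                math.lgamma(n + 1) - sum(math.lgamma(v + 1) for v in x)
                + math.lgamma(sum(a)) - math.lgamma(sum(a) + n)
                + sum(math.lgamma(ai + xi) - math.lgamma(ai)
                      for ai, xi in zip(a, x)))
    m = max(log_post)
    w = [math.exp(v - m) for v in log_post]
    return [v / sum(w) for v in w]


class TestOracleEquivalence:
    @pytest.mark.parametrize("experiment", ["exp1", "exp2", "exp3", "exp4"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_posterior_matches_brute_force(self, experiment, seed):
        rng = np.random.default_rng(seed)
        schema = schema_for(experiment)
        trials = []
        model = io.init_model(schema)
        for _ in range(40):
            label = int(rng.integers(1, 6))
            cond = str(rng.choice(["both", "conflict", "shape", "nonshape"]))
            if experiment.startswith("exp5"):
                cond = "nonshape"
            fv = extract(stimuli.sample_test_spec(experiment, cond, label, rng))
            trials.append((fv, label))
            io.update(model, fv, label)
        for _ in range(10):
            label = int(rng.integers(1, 6))
            fv = extract(stimuli.sample_test_spec(experiment, "both", label, rng)
                         if not experiment.startswith("exp5") else
                         stimuli.sample_test_spec(experiment, "nonshape", label, rng))
            got = io.posterior(model, fv).probabilities
            want = _oracle_posterior(schema, trials, fv)
            assert np.allclose(got, want, atol=1e-10)


# --------------------------------------------------------------------------
# prediction and evaluation
# --------------------------------------------------------------------------


class TestPrediction:
    def test_untrained_tie_breaks_to_lowest_class(self):
        model = io.init_model(schema_for("exp3"))
        rng = np.random.default_rng(0)
        fv = extract(stimuli.sample_test_spec("exp3", "both", 3, rng))
        assert io.predict(model, fv) == 1

    def test_predict_agrees_with_posterior_argmax(self, small_manifests):
        man, model = _fit_small(small_manifests, "exp4", "b")
        for spec in man.rows[:100]:
            fv = extract(spec)
            post = io.posterior(model, fv)
            assert io.predict(model, fv) == post.argmax_label()

    def test_evaluate_condition_untrained_is_chance(self, small_manifests):
        man = small_manifests("exp3", "a")
        model = io.init_model(schema_for("exp3"))
        mass, _acc = io.evaluate_condition(model, man.subset("both"))
        assert mass == pytest.approx(0.2, abs=1e-12)

    def test_evaluate_condition_rejects_bad_input(self, small_manifests):
        man, model = _fit_small(small_manifests, "exp3", "a")
        with pytest.raises(StimulusError):
            io.evaluate_condition(model, [])
        mixed = man.subset("both")[:2] + man.subset("shape")[:2]
        with pytest.raises(StimulusError):
            io.evaluate_condition(model, mixed)


# --------------------------------------------------------------------------
# scientific behaviour
# --------------------------------------------------------------------------


class TestBehaviour:
    @pytest.mark.parametrize("experiment,variant", ALL_DATASETS)
    def test_ground_truth_mapping_recovery(self, small_manifests,
                                           experiment, variant):
        """After training, each class's modal diagnostic value equals the
        generator's category->feature mapping."""
        man, model = _fit_small(small_manifests, experiment, variant,
                                n_train=200)
        kind = stimuli.FEATURE_KIND[experiment]
        for c in range(1, 6):
            if kind == "patch":
                # modal colour at the class's diagnostic location channel
                j_cat = model.schema.categorical_indices().index(c)
                modal = int(np.argmax(model.cat_counts[j_cat][c - 1]))
                assert modal == c  # value index c == colour c (lo==0)
            elif kind == "segment":
                assert int(np.argmax(model.block_counts[c - 1])) + 1 == c
            else:
                modal = int(np.argmax(model.cat_counts[1][c - 1]))
                assert modal + 1 == c

    def test_exp1a_conflict_patch_dominates_shape(self, small_manifests):
        man, model = _fit_small(small_manifests, "exp1", "a", n_train=500,
                                n_test=50)
        shape_mass, patch_mass = [], []
        for spec in man.subset("conflict"):
            post = io.posterior(model, extract(spec))
            shape_mass.append(post[spec.shape_id])
            patch_mass.append(post[spec.nonshape_category])
        assert np.mean(patch_mass) > np.mean(shape_mass)
        assert np.mean(patch_mass) > 0.9

    def test_relabelling_symmetry(self, small_manifests):
        """Permuting category labels permutes posteriors accordingly."""
        man = small_manifests("exp3", "a")
        perm = {1: 3, 2: 1, 3: 5, 4: 2, 5: 4}
        base = io.init_model(schema_for("exp3"))
        permuted = io.init_model(schema_for("exp3"))
        for spec in man.train_rows:
            fv = extract(spec)
            io.update(base, fv, spec.label)
            io.update(permuted, fv, perm[spec.label])
        for spec in man.subset("both")[:20]:
            fv = extract(spec)
            p = io.posterior(base, fv).probabilities
            q = io.posterior(permuted, fv).probabilities
            for c in range(1, 6):
                assert q[perm[c] - 1] == pytest.approx(p[c - 1], abs=1e-12)

    def test_both_condition_posterior_concentrates_with_training(self):
        """Variant-a Both-trial posterior mass is non-decreasing in the
        amount of training (checked across 5 dataset seeds)."""
        checkpoints = [50, 200, 800]
        for seed in range(5):
            df = io.learning_curve("exp4", "a", checkpoints, seed=seed,
                                   n_train=800, n_test_per_condition=50)
            curve = df[(df.condition == "both") & (df.metric == "mean_posterior")]
            vals = curve.sort_values("checkpoint")["value"].to_numpy()
            assert np.all(np.diff(vals) >= -0.01)


class TestLearningCurve:
    def test_checkpoint_zero_is_chance(self):
        df = io.learning_curve("exp3", "a", [0], seed=0, n_train=50,
                               n_test_per_condition=10)
        mass = df[df.metric == "mean_posterior"]["value"]
        assert np.allclose(mass, 0.2, atol=1e-12)

    def test_final_checkpoint_matches_full_fit(self, small_manifests):
        n_train, n_test, seed = 100, 20, 11
        df = io.learning_curve("exp2", "b", [50, n_train], seed=seed,
                               n_train=n_train, n_test_per_condition=n_test)
        man, model = _fit_small(small_manifests, "exp2", "b",
                                n_train=n_train, n_test=n_test)
        for cond in ("both", "conflict", "shape", "nonshape"):
            mass, acc = io.evaluate_condition(model, man.subset(cond))
            row = df[(df.checkpoint == n_train) & (df.condition == cond)]
            assert row[row.metric == "mean_posterior"]["value"].iloc[0] == \
                pytest.approx(mass, abs=1e-12)
            assert row[row.metric == "accuracy"]["value"].iloc[0] == \
                pytest.approx(acc, abs=1e-12)

    def test_checkpoint_beyond_dataset_rejected(self):
        with pytest.raises(StimulusError):
            io.learning_curve("exp3", "a", [100], n_train=50)

    def test_exp2b_tracks_both_cues_throughout(self):
        """Shape and Non-shape metrics are above chance from early
        checkpoints onward: the ideal observer learns both features."""
        df = io.learning_curve("exp2", "b", [100, 500, 1000, 2000], seed=0,
                               n_test_per_condition=100)
        for cond in ("shape", "nonshape"):
            vals = df[(df.condition == cond) & (df.metric == "mean_posterior")]
            assert (vals["value"] > 0.3).all()


class TestSerialisation:
    def test_json_round_trip(self, small_manifests, tmp_path):
        man, model = _fit_small(small_manifests, "exp2", "b")
        path = tmp_path / "model.json"
        io.to_json(model, path)
        loaded = io.from_json(path)
        for spec in man.rows[:20]:
            fv = extract(spec)
            assert np.allclose(io.posterior(model, fv).probabilities,
                               io.posterior(loaded, fv).probabilities,
                               atol=1e-15)
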