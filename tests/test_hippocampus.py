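"""The full hippocampal model: recall cascade, interference gating, learning."""

import numpy as np
import pytest

from hippobind import (
    BinaryPattern,
    HippocampalModel,
    ModelConfig,
    ValenceLayer,
    generate_exteroceptive,
    generate_stimulus_set,
    hamming_distance,
    make_valence,
    simple_hetero_model,
)


def bp(s):
    return BinaryPattern.from_string(s)


class TestWiring:
    def test_default_shapes(self):
        model = HippocampalModel(ModelConfig())
        assert model.W_e.w.shape == (300, 300)
        assert model.W_i.w.shape == (3, 3)
        assert model.W_ev.w.shape == (300, 15)  # 5 groups x 3 cells

    def test_single_group_has_no_inhibition(self):
        layer = ValenceLayer(p=1, m=3)
        assert layer.inhibition.sum() == 0

    def test_inhibition_is_later_onto_earlier_only(self):
        layer = ValenceLayer(p=3, m=2)
        groups = np.arange(6) // 2
        for i in range(6):
            for j in range(6):
                assert layer.inhibition[i, j] == (groups[i] > groups[j])

    def test_projection_aligns_valence_identity(self):
        layer = ValenceLayer(p=5, m=3)
        # cell at group 3, within-group position 2 targets interoceptive cell 2
        assert layer.projection[3 * 3 + 2].tolist() == [0, 0, 1]
        assert np.all(layer.projection.sum(axis=1) == 1)


class TestValenceActivation:
    def _model_with_excitation(self, groups_excited):
        # wire W_ev by hand so a 1-cell cue excites chosen (group, pos) cells
        model = HippocampalModel(ModelConfig(n=4, n_assoc_groups=2))
        for g, pos in groups_excited:
            model.W_ev.w[0, g * 3 + pos] = 1
        return model

    def test_later_group_silences_earlier(self):
        model = self._model_with_excitation([(0, 0), (1, 1)])
        exc, act = model.activate_valence(bp("1000"))
        assert exc.tolist() == [1, 0, 0, 0, 1, 0, 0, 0, 0]
        assert act.tolist() == [0, 0, 0, 0, 1, 0, 0, 0, 0]

    def test_single_group_passes_through(self):
        model = self._model_with_excitation([(0, 0), (0, 1)])
        exc, act = model.activate_valence(bp("1000"))
        assert np.array_equal(exc, act)

    def test_zero_input_yields_zero(self):
        model = self._model_with_excitation([(0, 0)])
        exc, act = model.activate_valence(bp("0000"))
        assert exc.sum() == 0 and act.sum() == 0


class TestInteroPrediction:
    def test_single_valence_cell_recalls_one_hot(self):
        model = HippocampalModel(ModelConfig(n=4))
        model.W_i.store_auto(make_valence("positive"))
        y = np.zeros(15, dtype=np.uint8)
        y[2 * 3 + 0] = 1  # positive cell of group 2
        tilde, pred = model.predict_intero(y)
        assert tilde == make_valence("positive")
        assert pred == make_valence("positive")

    def test_conflicting_cells_in_one_group_predict_nothing(self):
        # two active valence cells raise theta to 2; a diagonal-only W_i
        # cannot reach it, so the prediction is empty
        model = HippocampalModel(ModelConfig(n=4))
        model.W_i.store_auto(make_valence("positive"))
        model.W_i.store_auto(make_valence("negative"))
        y = np.zeros(15, dtype=np.uint8)
        y[0] = y[1] = 1
        tilde, pred = model.predict_intero(y)
        assert tilde.n_active == 2
        assert pred.n_active == 0

    def test_zero_activity_predicts_nothing(self):
        model = HippocampalModel(ModelConfig(n=4))
        _, pred = model.predict_intero(np.zeros(15, dtype=np.uint8))
        assert pred.n_active == 0


class TestInterferenceDetection:
    def _result_with_group_activity(self, model, k, bits):
        act = np.zeros(model.layer.size, dtype=np.uint8)
        act[model.layer.group_slice(k)] = bits
        from hippobind.hippocampus import RecallResult

        zero = BinaryPattern.zeros(model.config.n)
        zerom = BinaryPattern.zeros(model.config.m)
        return RecallResult(zero, act.copy(), act, zerom, zerom)

    def test_mismatching_active_group_flags_and_gates_next(self):
        model = HippocampalModel(ModelConfig(n=4))
        res = self._result_with_group_activity(model, 0, [1, 1, 0])
        gating = model.detect_interference(res, make_valence("positive"))
        assert gating.xi == (1, 0, 0, 0, 0)
        assert gating.gate == (1, 1, 0, 0, 0)

    def test_silent_layer_raises_no_flag(self):
        model = HippocampalModel(ModelConfig(n=4))
        res = self._result_with_group_activity(model, 0, [0, 0, 0])
        gating = model.detect_interference(res, make_valence("positive"))
        assert gating.xi == (0, 0, 0, 0, 0)
        assert gating.gate == (1, 0, 0, 0, 0)

    def test_matching_activity_raises_no_flag(self):
        model = HippocampalModel(ModelConfig(n=4))
        res = self._result_with_group_activity(model, 0, [1, 0, 0])
        gating = model.detect_interference(res, make_valence("positive"))
        assert gating.xi == (0, 0, 0, 0, 0)

    def test_threshold_v_grants_tolerance(self):
        model = HippocampalModel(ModelConfig(n=4, v=2))
        res = self._result_with_group_activity(model, 0, [0, 0, 1])
        # HD = 2 is not > v = 2: recognized despite the mismatch
        gating = model.detect_interference(res, make_valence("positive"))
        assert gating.xi == (0, 0, 0, 0, 0)


class TestLearning:
    def test_fresh_trial_learns_into_primary_group(self, rng, valences):
        model = HippocampalModel(ModelConfig())
        a = generate_exteroceptive(300, 8, rng)
        rec = model.process_trial(a, valences["positive"])
        assert rec.extero_novel and rec.learned
        assert rec.group_used == 0
        assert model.groups_in_use() == 0  # no associated group touched

    def test_single_trial_acquisition(self, rng, valences):
        model = HippocampalModel(ModelConfig())
        a = generate_exteroceptive(300, 8, rng)
        model.process_trial(a, valences["negative"])
        rec = model.process_trial(a, valences["negative"])
        assert rec.completion_hd == 0 and rec.prediction_hd == 0
        assert not rec.learned

    def test_interference_recruits_next_group_and_silences_primary(
        self, feature_stimuli, valences
    ):
        model = HippocampalModel(ModelConfig(n=16))
        model.process_trial(feature_stimuli("AB"), valences["positive"])
        model.process_trial(feature_stimuli("AC"), valences["negative"])
        model.process_trial(feature_stimuli("BD"), valences["negative"])
        rec = model.process_trial(feature_stimuli("AB"), valences["positive"])
        assert rec.interference_detected
        assert rec.group_used == 1
        # the re-encoding lives in group 1 only: group-0 columns unchanged
        g1 = model.W_ev.w[:, model.layer.group_slice(1)]
        assert g1[:, 0].sum() == 8 and g1[:, 1:].sum() == 0

    def test_figure2_scenario_end_to_end(self, feature_stimuli, valences):
        model = HippocampalModel(ModelConfig(n=16))
        trio = [("AB", "positive"), ("AC", "negative"), ("BD", "negative")]
        for name, lab in trio:
            model.process_trial(feature_stimuli(name), valences[lab])
        # presentation of AB drives both primary valence cells
        rec = model.process_trial(feature_stimuli("AB"), valences["positive"])
        assert rec.recall.valence_excitation[:3].tolist() == [1, 1, 0]
        assert rec.recall.predicted_intero.n_active == 0
        assert rec.valence_error and rec.interference_detected and rec.learned
        # next presentation predicts the correct valence from group 1
        rec2 = model.process_trial(feature_stimuli("AB"), valences["positive"])
        assert rec2.prediction_hd == 0 and not rec2.learned

    def test_interference_resolved_within_two_passes(
        self, feature_stimuli, valences
    ):
        model = HippocampalModel(ModelConfig(n=16))
        trio = [("AB", "positive"), ("AC", "negative"), ("BD", "negative")]
        for _ in range(2):
            for name, lab in trio:
                model.process_trial(feature_stimuli(name), valences[lab])
        for name, lab in trio:
            rec = model.process_trial(
                feature_stimuli(name), valences[lab], learning_enabled=False
            )
            assert rec.prediction_hd == 0

    def test_capacity_exhaustion_skips_heteroassociative_update(
        self, feature_stimuli, valences
    ):
        # p = 2: one associated group; drive interference onto it and then
        # change the valence once more, leaving no group to recruit
        model = HippocampalModel(ModelConfig(n=16, n_assoc_groups=1))
        model.process_trial(feature_stimuli("AB"), valences["positive"])
        model.process_trial(feature_stimuli("AC"), valences["negative"])
        model.process_trial(feature_stimuli("BD"), valences["negative"])
        rec = model.process_trial(feature_stimuli("AB"), valences["positive"])
        assert rec.group_used == 1  # re-encoded into the last group
        before_ev = model.W_ev.w.copy()
        before_i = model.W_i.w.copy()
        rec = model.process_trial(feature_stimuli("AB"), valences["neutral"])
        assert rec.capacity_exhausted and rec.group_used is None
        assert np.array_equal(model.W_ev.w, before_ev)  # skipped
        assert not np.array_equal(model.W_i.w, before_i)  # autoassoc proceeds

    def test_learning_disabled_leaves_state_untouched(self, rng, valences):
        model = HippocampalModel(ModelConfig())
        a = generate_exteroceptive(300, 8, rng)
        snap = model.snapshot()
        rec = model.process_trial(a, valences["positive"], learning_enabled=False)
        assert rec.extero_novel and not rec.learned
        assert model.snapshot() == snap


class TestInvariants:
    def _random_trials(self, model, n_trials, seed, n, k):
        rng = np.random.default_rng(seed)
        stimuli = generate_stimulus_set(n_trials, n, k, rng)
        records = []
        for pair in stimuli:
            records.append(model.process_trial(pair.extero, pair.intero))
        return records

    def test_activity_never_spans_two_groups_and_prediction_one_hot(self):
        model = HippocampalModel(ModelConfig(n=30))
        records = self._random_trials(model, 60, seed=5, n=30, k=5)
        for rec in records:
            act = rec.recall.valence_activity
            assert len(model.layer.active_groups(act)) <= 1
            assert rec.recall.predicted_intero.n_active in (0, 1)

    def test_learned_flag_equals_novelty_or_error(self):
        model = HippocampalModel(ModelConfig(n=30))
        for rec in self._random_trials(model, 60, seed=6, n=30, k=5):
            assert rec.learned == (rec.extero_novel or rec.valence_error)

    def test_weights_are_monotone_across_trials(self):
        model = HippocampalModel(ModelConfig(n=30))
        rng = np.random.default_rng(7)
        stimuli = generate_stimulus_set(40, 30, 5, rng)
        prev = model.snapshot()
        for pair in stimuli:
            model.process_trial(pair.extero, pair.intero)
            for key in ("W_e", "W_i", "W_ev"):
                old = np.array([[int(c) for c in r] for r in prev[key]["w"]])
                new_mat = getattr(model, key).w
                assert np.all(new_mat >= old)
            prev = model.snapshot()


class TestSingleGroupEquivalence:
    """The p=1 model must behave exactly like a plain heteroassociative
    pipeline: complete, threshold onto 3 valence cells, recall the valence."""

    @staticmethod
    def straight_line_oracle(stored, cue_bits, n):
        # independent implementation with dense integer matrices
        W_e = np.zeros((n, n), int)
        W_ev = np.zeros((n, 3), int)
        W_i = np.zeros((3, 3), int)
        for x, y in stored:
            W_e |= np.outer(x, x)
            W_ev |= np.outer(x, y)
            W_i |= np.outer(y, y)
        th = cue_bits.sum()
        ae = (W_e.T @ cue_bits >= th) if th else np.zeros(n, bool)
        th2 = ae.sum()
        yv = (W_ev.T @ ae.astype(int) >= th2) if th2 else np.zeros(3, bool)
        th3 = yv.sum()
        ai = (W_i.T @ yv.astype(int) >= th3) if th3 else np.zeros(3, bool)
        return ae.astype(int), ai.astype(int)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_trialwise_equality_with_oracle(self, seed):
        n = 50
        rng = np.random.default_rng(seed)
        stimuli = generate_stimulus_set(30, n, 6, rng)
        model = simple_hetero_model(ModelConfig(n=n))
        stored = []
        for pair in stimuli:
            ae, ai = self.straight_line_oracle(
                stored, pair.extero.bits.astype(int), n
            )
            rec = model.process_trial(pair.extero, pair.intero)
            assert rec.recall.completed_extero.bits.tolist() == ae.tolist()
            assert rec.recall.predicted_intero.bits.tolist() == ai.tolist()
            # oracle stores whenever the model entered learning mode
            if rec.learned:
                stored.append(
                    (pair.extero.bits.astype(int), pair.intero.bits.astype(int))
                )

    def test_simple_hetero_is_the_p1_model(self):
        model = simple_hetero_model(ModelConfig(n=20))
        assert isinstance(model, HippocampalModel)
        assert model.config.p == 1

    def test_p1_conflict_is_relearned_into_primary(self, feature_stimuli, valences):
        # with no associated groups a valence conflict is written straight
        # over the primary group and keeps interfering
        model = simple_hetero_model(ModelConfig(n=16))
        model.process_trial(feature_stimuli("AB"), valences["positive"])
        model.process_trial(feature_stimuli("AC"), valences["negative"])
        model.process_trial(feature_stimuli("BD"), valences["negative"])
        for _ in range(3):
            rec = model.process_trial(feature_stimuli("AB"), valences["positive"])
            assert rec.valence_error and rec.learned
            assert rec.group_used == 0 and not rec.capacity_exhausted


class TestSnapshots:
    def test_roundtrip_preserves_behaviour(self, tmp_path, rng, valences):
        model = HippocampalModel(ModelConfig(n=40))
        stimuli = generate_stimulus_set(10, 40, 5, rng)
        for pair in stimuli:
            model.process_trial(pair.extero, pair.intero)
        path = tmp_path / "model.json"
        model.save(path)
        clone = HippocampalModel.load(path)
        probe = generate_exteroceptive(40, 5, rng)
        a = model.process_trial(probe, valences["neutral"], learning_enabled=False)
        b = clone.process_trial(probe, valences["neutral"], learning_enabled=False)
        assert a.completion_hd == b.completion_hd
        assert a.prediction_hd == b.prediction_hd
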