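"""Two-state epitope scorer: training, forward-backward posterior, mixing."""

import itertools

import numpy as np
import pytest

from allermap.bepipred import (
    BACKGROUND,
    EPITOPE,
    ScoreProfile,
    TwoStateModel,
    bepipred_like_profile,
    posterior_profile,
    standardize,
    train_two_state,
)
from allermap.propensity import windowed_mean_profile
from allermap.scales import SCALE_PARKER
from allermap.seqio import STANDARD_AA, ProteinRecord
from allermap.synthetic import PlantSpec, generate_protein

AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


def random_model(rng) -> TwoStateModel:
    emis = rng.random((2, 20)) + 0.05
    emis /= emis.sum(axis=1, keepdims=True)
    trans = rng.random((2, 2)) + 0.05
    trans /= trans.sum(axis=1, keepdims=True)
    return TwoStateModel(emis, trans, 0.5)


def posterior_oracle(seq: str, model: TwoStateModel) -> np.ndarray:
    """Marginalise the epitope state over all 2^n explicit paths."""
    n = len(seq)
    pi = model.stationary()
    total = np.zeros(n)
    z = 0.0
    for path in itertools.product((EPITOPE, BACKGROUND), repeat=n):
        p = pi[path[0]] * model.emissions[path[0], AA_INDEX[seq[0]]]
        for t in range(1, n):
            p *= (model.transitions[path[t - 1], path[t]]
                  * model.emissions[path[t], AA_INDEX[seq[t]]])
        z += p
        for t in range(n):
            if path[t] == EPITOPE:
                total[t] += p
    return total / z


class TestTraining:
    def test_fully_epitope_sequence_gives_smoothed_composition(self):
        rec = ProteinRecord("p", "KKEEG")
        model = train_two_state([(rec, [(1, 5)])])
        counts = np.ones(20)
        for aa in rec.residues:
            counts[AA_INDEX[aa]] += 1
        assert np.allclose(model.emissions[EPITOPE], counts / counts.sum())

    def test_no_transitions_leaves_smoothing_floor(self):
        rec = ProteinRecord("p", "KKKKK")
        model = train_two_state([(rec, [(1, 5)])])
        # all 4 observed pairs are epitope->epitope; off-diagonal is floor
        assert model.transitions[EPITOPE, BACKGROUND] == pytest.approx(1 / 6)
        # background row saw nothing: stays uniform
        assert np.allclose(model.transitions[BACKGROUND], 0.5)

    def test_lysine_rich_epitopes_shift_emissions(self):
        corpus = []
        for seed in range(5):
            rec, truth = generate_protein(PlantSpec(length=120, seed=seed))
            corpus.append((rec, truth))
        model = train_two_state(corpus)
        k = AA_INDEX["K"]
        assert model.emissions[EPITOPE, k] > model.emissions[BACKGROUND, k]

    def test_out_of_bounds_interval_rejected(self):
        rec = ProteinRecord("p", "KKKKK")
        with pytest.raises(ValueError, match="outside"):
            train_two_state([(rec, [(3, 9)])])

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            train_two_state([])


class TestPosterior:
    def test_uninformative_emissions_give_stationary_posterior(self):
        emis = np.full((2, 20), 1 / 20)
        trans = np.array([[0.9, 0.1], [0.3, 0.7]])
        model = TwoStateModel(emis, trans)
        post = posterior_profile(ProteinRecord("p", "MKVLAQ"), model)
        stationary_epitope = model.stationary()[EPITOPE]
        assert np.allclose(post.values, stationary_epitope)

    def test_posteriors_are_probabilities(self, record_50mer):
        model = random_model(np.random.default_rng(0))
        post = posterior_profile(record_50mer, model)
        assert ((post.values >= 0) & (post.values <= 1)).all()

    def test_matches_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(1, 9))
            seq = "".join(rng.choice(list(STANDARD_AA), size=n))
            model = random_model(rng)
            post = posterior_profile(ProteinRecord("p", seq), model)
            assert np.allclose(post.values, posterior_oracle(seq, model),
                               atol=1e-10)


class TestMixedScore:
    def test_w1_is_pure_rescaled_posterior(self, record_50mer):
        model = random_model(np.random.default_rng(1))
        model = TwoStateModel(model.emissions, model.transitions, 1.0)
        parker = windowed_mean_profile(record_50mer, SCALE_PARKER)
        score = bepipred_like_profile(record_50mer, model, parker)
        post = posterior_profile(record_50mer, model)
        assert np.allclose(score.values, 2 * post.values - 1)

    def test_w0_is_pure_standardised_parker(self, record_50mer):
        model = random_model(np.random.default_rng(2))
        model = TwoStateModel(model.emissions, model.transitions, 0.0)
        parker = windowed_mean_profile(record_50mer, SCALE_PARKER)
        score = bepipred_like_profile(record_50mer, model, parker)
        assert np.allclose(score.values, standardize(parker.values))

    def test_planted_segment_scores_above_background(self):
        spec = PlantSpec(length=100, segments=((40, 59),), seed=9)
        rec, truth = generate_protein(spec)
        model = train_two_state([(rec, truth)])
        parker = windowed_mean_profile(rec, SCALE_PARKER)
        score = bepipred_like_profile(rec, model, parker)
        inside = score.values[39:59]
        outside = np.concatenate([score.values[:39], score.values[59:]])
        assert inside.mean() > outside.mean()

    def test_score_ignores_id_and_description(self, record_50mer):
        model = random_model(np.random.default_rng(3))
        parker = windowed_mean_profile(record_50mer, SCALE_PARKER)
        other = ProteinRecord("renamed", record_50mer.residues,
                              "different description")
        a = bepipred_like_profile(record_50mer, model, parker)
        b = bepipred_like_profile(other, model, parker)
        assert np.array_equal(a.values, b.values)

    def test_training_ranks_planted_residues_above_background(self):
        # averaged over seeds, epitope residues outscore background on the
        # training corpus itself
        wins = 0
        for seed in range(20):
            rec, truth = generate_protein(PlantSpec(length=150, seed=seed))
            model = train_two_state([(rec, truth)])
            parker = windowed_mean_profile(rec, SCALE_PARKER)
            score = bepipred_like_profile(rec, model, parker)
            mask = np.zeros(len(rec), dtype=bool)
            for s, e in truth:
                mask[s - 1 : e] = True
            if score.values[mask].mean() > score.values[~mask].mean():
                wins += 1
        assert wins >= 18

    def test_length_mismatch_rejected(self, record_50mer):
        model = random_model(np.random.default_rng(4))
        short = windowed_mean_profile(
            ProteinRecord("s", record_50mer.residues[:-1]), SCALE_PARKER)
        with pytest.raises(ValueError, match="length"):
            bepipred_like_profile(record_50mer, model, short)


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        model = random_model(np.random.default_rng(5))
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = TwoStateModel.from_json(path)
        assert np.allclose(loaded.emissions, model.emissions)
        assert np.allclose(loaded.transitions, model.transitions)
        assert loaded.mixing_weight == model.mixing_weight

    def test_invalid_rows_rejected(self):
        bad = np.full((2, 20), 0.06)
        with pytest.raises(ValueError, match="sum to 1"):
            TwoStateModel(bad, np.array([[0.5, 0.5], [0.5, 0.5]]))
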