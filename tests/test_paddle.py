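import numpy as np
import pytest

from adscreen.paddle import (CompositionMLP, PADDLERegressor, PredictionTrack,
                             call_predicted_ads, composition_matrix,
                             encode_fragment, encode_sequences, find_core_ads,
                             insilico_scan, moving_average, predict_protein,
                             predict_short)
from adscreen.seq_features import AMINO_ACIDS


class CountModel:
    """Stand-in predictor: Z = weighted residue counts of each 53-aa tile.

    Order-blind and training-free, used to exercise the prediction-time
    procedures with analytically known outputs.
    """

    def __init__(self, weights: dict[str, float]):
        self.w = np.zeros(20, dtype=np.float32)
        for aa, wt in weights.items():
            self.w[AMINO_ACIDS.index(aa)] = wt

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (X[:, :, :20] * self.w).sum(axis=(1, 2))


class TestEncoding:
    def test_one_hot_rows_sum_to_one(self, random_peptides):
        for seq in random_peptides(5, 53):
            m = encode_fragment(seq)
            assert m.shape == (53, 20)
            assert np.allclose(m.sum(axis=1), 1.0)

    def test_full_variant_shape_and_bounds(self, rng):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=53))
        ss = rng.random((53, 2))
        dis = rng.random((53, 2))
        m = encode_fragment(seq, ss, dis, variant="full")
        assert m.shape == (53, 24)
        assert (m[:, 20:] >= 0).all() and (m[:, 20:] <= 1).all()

    def test_single_substitution_changes_one_row(self):
        a = "A" * 53
        b = "A" * 20 + "W" + "A" * 32
        da, db = encode_fragment(a), encode_fragment(b)
        diff_rows = np.flatnonzero((da != db).any(axis=1))
        assert list(diff_rows) == [20]

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            encode_fragment("ACD")

    def test_composition_vector(self):
        v = composition_matrix(["D" * 53])[0]
        assert v[AMINO_ACIDS.index("D")] == pytest.approx(1.0)
        assert v.sum() == pytest.approx(1.0)


class TestMovingAverage:
    def test_constant_track_unchanged(self):
        x = np.full(30, 4.0)
        assert np.allclose(moving_average(x), x)

    def test_impulse_spreads_over_window(self):
        x = np.zeros(30)
        x[15] = 9.0
        sm = moving_average(x, window=9)
        assert np.allclose(sm[11:20], 1.0)
        assert sm[10] == 0.0 and sm[20] == 0.0

    def test_edges_truncate(self):
        x = np.zeros(20)
        x[0] = 5.0
        sm = moving_average(x, window=9)
        assert sm[0] == pytest.approx(5.0 / 5)  # window [0, 5)


class TestPredictProtein:
    def test_track_length_and_smoothing(self, random_peptides):
        protein = random_peptides(1, 100)[0]
        model = CountModel({"W": 1.0})
        track = predict_protein(model, protein, "p")
        assert track.raw.shape == (100 - 52,)
        assert track.smoothed.shape == track.raw.shape
        assert np.allclose(track.smoothed, moving_average(track.raw))

    def test_short_protein_rejected(self):
        with pytest.raises(ValueError):
            predict_protein(CountModel({}), "ACDEF", "p")


def _track(values):
    v = np.asarray(values, dtype=float)
    return PredictionTrack("p", v, v)  # already-smoothed toy track


class TestCallPredictedAds:
    def test_four_consecutive_tiles_insufficient(self):
        z = np.zeros(60)
        z[10:14] = 7.0  # only 4 consecutive starts above 6
        assert call_predicted_ads(_track(z)) == []

    def test_five_consecutive_tiles_called(self):
        z = np.zeros(60)
        z[10:15] = 7.0
        calls = call_predicted_ads(_track(z))
        assert len(calls) == 1
        assert (calls[0].start, calls[0].stop) == (10, 14 + 53)
        assert calls[0].strength == "high"

    def test_high_and_medium_separated(self):
        # one run at Z=6.5 and a distant run at Z=4.5
        z = np.zeros(250)
        z[10:20] = 6.5
        z[150:160] = 4.5
        calls = call_predicted_ads(_track(z))
        assert [c.strength for c in calls] == ["high", "medium"]
        assert (calls[0].start, calls[0].stop) == (10, 19 + 53)
        assert (calls[1].start, calls[1].stop) == (150, 159 + 53)

    def test_medium_overlapping_high_discarded(self):
        # the medium-strength run sits just beside the high run: its tile
        # union overlaps the high call by more than 26 aa
        z = np.zeros(250)
        z[10:20] = 6.5
        z[20:30] = 4.5
        calls = call_predicted_ads(_track(z))
        assert [c.strength for c in calls] == ["high"]

    def test_overlapping_high_runs_merge(self):
        z = np.zeros(250)
        z[10:20] = 6.5
        z[30:40] = 8.0  # tile spans overlap the first run by > 26 aa
        calls = call_predicted_ads(_track(z))
        assert len(calls) == 1
        assert (calls[0].start, calls[0].stop) == (10, 39 + 53)
        assert calls[0].peak_z == 8.0


class TestPredictShort:
    def test_contexts_use_neutral_alphabet_and_determinism(self):
        model = CountModel({"W": 1.0, "A": 0.0})
        # W appears only in the query; neutral AGSTNQV context adds nothing
        z = predict_short(model, "WWWWW", n_contexts=10, rng_seed=0)
        assert z == pytest.approx(5.0)
        z2 = predict_short(model, "WWWWW", n_contexts=10, rng_seed=0)
        assert z == z2

    def test_context_variance_shrinks_with_averaging(self):
        model = CountModel({"Q": 1.0})  # context-sensitive score
        few = [predict_short(model, "WWWWW", n_contexts=2, rng_seed=s) for s in range(30)]
        many = [predict_short(model, "WWWWW", n_contexts=50, rng_seed=s) for s in range(30)]
        assert np.var(many) < np.var(few) / 5

    def test_full_tile_rejected(self):
        with pytest.raises(ValueError):
            predict_short(CountModel({}), "A" * 53)


class TestFindCoreAds:
    def test_no_qualifying_subtile(self):
        model = CountModel({"W": 1.0})
        protein = "A" * 100  # no W anywhere: all Z = 0 < 3.09
        assert find_core_ads(model, protein, (20, 60), n_contexts=3) == []

    def test_shortest_qualifying_tile_selected(self):
        model = CountModel({"W": 1.0})
        protein = "A" * 40 + "WWWWW" + "A" * 40
        cores = find_core_ads(model, protein, (30, 60), n_contexts=3)
        assert len(cores) == 1
        # the 4-W 5-mers at offsets 39..45 qualify (Z=4); ties resolve to the
        # leftmost full-W window with Z=5 at [40, 45)
        assert (cores[0].start, cores[0].stop) == (40, 45)
        assert cores[0].z == pytest.approx(5.0)

    def test_overlapping_longer_tile_skipped(self):
        model = CountModel({"W": 1.0})
        protein = "A" * 40 + "WWWWWWWWWW" + "A" * 40
        cores = find_core_ads(model, protein, (35, 55), n_contexts=3)
        for a, b in zip(cores, cores[1:]):
            assert a.stop <= b.start  # non-overlapping by construction
        assert all(c.stop - c.start == 5 for c in cores)


class TestInsilicoScan:
    def test_substitution_identity_positions_zero(self):
        model = CountModel({"W": 1.0})
        core = "AWAWA"
        dz = insilico_scan(model, core, substitution="A", n_contexts=4)
        assert dz.shape == (5,)
        assert dz[0] == 0.0 and dz[2] == 0.0 and dz[4] == 0.0

    def test_tryptophan_positions_lose_signal(self):
        model = CountModel({"W": 1.0})
        dz = insilico_scan(model, "WWDWW", substitution="A", n_contexts=4)
        assert np.allclose(dz[[0, 1, 3, 4]], -1.0)
        assert dz[2] == 0.0  # D -> A is neutral under this model


class TestEstimators:
    def test_constant_target_learned(self, rng):
        X = rng.random((60, 20)).astype(np.float32)
        y = np.full(60, 3.7)
        mlp = CompositionMLP(n_folds=2, max_epochs=5, random_state=0)
        mlp.fit(X, y)
        assert np.allclose(mlp.predict(X), 3.7, atol=0.05)

    def test_prediction_is_member_mean(self, rng):
        X = rng.random((60, 20)).astype(np.float32)
        y = rng.normal(size=60)
        mlp = CompositionMLP(n_folds=3, max_epochs=3, random_state=0)
        mlp.fit(X, y)
        members = mlp._member_predictions(X)
        assert members.shape[0] == 3
        assert np.allclose(mlp.predict(X), members.mean(axis=0))

    def test_grouped_folds_respect_proteins(self, rng):
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), size=53)) for _ in range(40)]
        X = encode_sequences(seqs)
        y = rng.normal(size=40)
        groups = np.repeat(np.arange(8), 5)
        cnn = PADDLERegressor(n_conv_layers=1, channels=4, kernel_size=5,
                              n_folds=2, max_epochs=2, random_state=0)
        cnn.fit(X, y, groups=groups)
        assert len(cnn.models_) == 2
        assert cnn.predict(X).shape == (40,)

    def test_sklearn_params_round_trip(self):
        cnn = PADDLERegressor(channels=7)
        assert cnn.get_params()["channels"] == 7
        cnn.set_params(channels=9)
        assert cnn.get_params()["channels"] == 9


class TestNetworkGradients:
    def test_analytic_gradients_match_numeric(self, rng):
        """Backprop through conv/batch-norm/swish/max-pool/dense agrees with
        central-difference gradients."""
        from adscreen.paddle._nn import (BatchNorm, Conv1D, Dense,
                                         GlobalMaxPool, Network, Swish)

        x = rng.standard_normal((8, 12, 4)).astype(np.float32)
        y = rng.standard_normal((8, 1)).astype(np.float32)
        net = Network([
            Conv1D(4, 6, 3, rng), BatchNorm(6), Swish(), GlobalMaxPool(),
            Dense(6, 5, rng), Swish(), Dense(5, 1, rng),
        ])

        def loss():
            return float(((net.forward(x, training=True) - y) ** 2).mean())

        pred = net.forward(x, training=True)
        net.backward(2 * (pred - y) / y.shape[0])
        eps = 1e-3
        for layer in net.layers:
            for p, g in zip(layer.params, layer.grads):
                idx = tuple(int(rng.integers(0, s)) for s in p.shape)
                old = p[idx]
                p[idx] = old + eps
                lp = loss()
                p[idx] = old - eps
                lm = loss()
                p[idx] = old
                numeric = (lp - lm) / (2 * eps)
                assert g[idx] == pytest.approx(numeric, rel=0.02, abs=1e-4)
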