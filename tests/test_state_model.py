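"""PCA, HMM fitting/decoding, the variance-ratio criterion and fragments."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import calinski_harabasz_score

from chromband.genomic_io import SignalMatrix, build_bins
from chromband.state_model import (
    HMMModel,
    PCView,
    ReferenceAnchors,
    StatePath,
    anchor_and_extract,
    calinski_harabasz,
    fit_hmm,
    name_states,
    path_to_fragments,
    pca_scores,
    select_state_count,
    viterbi_decode,
)
from _oracles import brute_force_viterbi, calinski_harabasz_by_hand


def _signal(values: np.ndarray, names=None, chrom_sizes=None):
    n, d = values.shape
    names = names or [f"d{i}" for i in range(d)]
    bins = build_bins(chrom_sizes or {"chrX": n * 200}, 200)
    return SignalMatrix(bins, names, values, np.zeros_like(values, dtype=bool))


def _view(scores: np.ndarray, chrom_sizes=None, mask=None):
    n, d = scores.shape
    bins = build_bins(chrom_sizes or {"chrX": n * 200}, 200)
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    sc = np.where(mask[:, None], np.nan, scores)
    return PCView(bins, sc, mask, np.eye(d), np.ones(d) / d)


class TestPCA:
    def test_one_dimensional_data_loads_on_single_component(self):
        t = np.linspace(-1, 1, 50)
        values = np.column_stack([t, t]) / np.sqrt(2)
        view = pca_scores(_signal(values), n_components=2)
        assert view.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_uncorrelated_unit_variance_splits_evenly(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(4000, 2))
        view = pca_scores(_signal(values), n_components=2)
        assert view.explained_variance_ratio[0] == pytest.approx(0.5, abs=0.05)

    def test_rotation_leaves_spectrum_unchanged(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(500, 2)) @ np.diag([2.0, 0.5])
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        v1 = pca_scores(_signal(values), n_components=2).explained_variance_ratio
        v2 = pca_scores(_signal(values @ R), n_components=2).explained_variance_ratio
        np.testing.assert_allclose(v1, v2, atol=1e-10)

    def test_masked_bins_flagged_and_excluded(self):
        values = np.random.default_rng(2).normal(size=(30, 3))
        mask = np.zeros_like(values, dtype=bool)
        mask[5, 1] = True
        sm = _signal(values)
        sm.mask[:] = mask
        sm.values[mask] = np.nan
        view = pca_scores(sm, n_components=2)
        assert view.mask[5] and np.isnan(view.scores[5]).all()
        assert view.n_usable == 29


class TestFitHMM:
    def test_single_state_closed_form(self):
        rng = np.random.default_rng(3)
        view = _view(rng.normal(size=(200, 2)))
        model = fit_hmm(view, K=1, seed=0, n_restarts=1, max_iter=5)
        np.testing.assert_allclose(model.means[0], view.scores.mean(axis=0), atol=1e-6)
        np.testing.assert_allclose(model.transmat, [[1.0]])

    def test_two_blob_mean_recovery(self):
        rng = np.random.default_rng(4)
        z = rng.random(600) < 0.5
        X = np.where(z[:, None], 10.0, 0.0) + rng.normal(size=(600, 2))
        model = fit_hmm(_view(X), K=2, seed=0, n_restarts=2)
        got = sorted(model.means[:, 0])
        assert abs(got[0] - 0.0) < 0.2 and abs(got[1] - 10.0) < 0.2

    def test_em_likelihood_improves_with_iterations(self):
        rng = np.random.default_rng(5)
        X = np.concatenate([rng.normal(0, 1, (150, 2)), rng.normal(3, 1, (150, 2))])
        short = fit_hmm(_view(X), K=2, seed=0, n_restarts=1, max_iter=1, tol=0)
        longer = fit_hmm(_view(X), K=2, seed=0, n_restarts=1, max_iter=10, tol=0)
        assert longer.log_likelihood >= short.log_likelihood - 1e-8

    def test_too_few_bins_rejected(self):
        view = _view(np.zeros((25, 2)))
        with pytest.raises(ValueError, match="10\\*K"):
            fit_hmm(view, K=3, seed=0)


def _random_model(rng, K, d=2):
    startprob = rng.dirichlet(np.ones(K))
    transmat = rng.dirichlet(np.ones(K), size=K)
    means = rng.normal(0, 3, size=(K, d))
    covars = np.array([np.eye(d) * rng.uniform(0.5, 2.0) for _ in range(K)])
    return HMMModel(K=K, startprob=startprob, transmat=transmat, means=means,
                    covars=covars, log_likelihood=0.0, seed=0)


class TestViterbi:
    def test_single_state_paths_are_constant(self):
        view = _view(np.random.default_rng(6).normal(size=(20, 2)))
        model = fit_hmm(view, K=1, seed=0, n_restarts=1, max_iter=2)
        path = viterbi_decode(model, view)
        assert (path.states == 0).all()

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            K = int(rng.integers(2, 4))
            T = int(rng.integers(2, 9))
            model = _random_model(rng, K)
            X = rng.normal(0, 3, size=(T, 2))
            path = viterbi_decode(model, _view(X))
            expected = brute_force_viterbi(model.startprob, model.transmat,
                                           model.means, model.covars, X)
            np.testing.assert_array_equal(path.states, expected)

    def test_near_identity_transitions_give_nearest_mean_labels(self):
        rng = np.random.default_rng(8)
        means = np.array([[0.0, 0.0], [50.0, 50.0]])
        labels = (rng.random(100) < 0.5).astype(int)
        X = means[labels] + rng.normal(0, 0.5, (100, 2))
        model = HMMModel(
            K=2, startprob=np.array([0.5, 0.5]),
            transmat=np.array([[0.5, 0.5], [0.5, 0.5]]),
            means=means, covars=np.array([np.eye(2), np.eye(2)]),
            log_likelihood=0.0, seed=0)
        path = viterbi_decode(model, _view(X))
        np.testing.assert_array_equal(path.states, labels)

    def test_masked_bins_break_chain_and_stay_missing(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 2))
        mask = np.zeros(30, dtype=bool)
        mask[10:13] = True
        view = _view(X, mask=mask)
        model = fit_hmm(view, K=1, seed=0, n_restarts=1, max_iter=2)
        path = viterbi_decode(model, view)
        assert (path.states[10:13] == -1).all()
        assert (path.states[:10] == 0).all() and (path.states[13:] == 0).all()

    def test_all_masked_chromosome_warns(self):
        view = _view(np.random.default_rng(10).normal(size=(20, 2)))
        model = fit_hmm(view, K=1, seed=0, n_restarts=1, max_iter=2)
        empty = _view(np.zeros((5, 2)), mask=np.ones(5, dtype=bool))
        with pytest.warns(UserWarning, match="all bins masked"):
            path = viterbi_decode(model, empty)
        assert (path.states == -1).all()


class TestCalinskiHarabasz:
    def test_requires_at_least_two_states(self):
        view = _view(np.zeros((10, 2)))
        with pytest.raises(ValueError, match="K >= 2"):
            calinski_harabasz(view, StatePath(np.zeros(10, dtype=int), K=1))

    def test_zero_within_dispersion_returns_infinity(self):
        view = _view(np.array([[0.0, 0.0], [5.0, 5.0]]))
        path = StatePath(np.array([0, 1]), K=2)
        assert calinski_harabasz(view, path) == np.inf

    def test_hand_expanded_four_point_example(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        labels = np.array([0, 0, 1, 1])
        got = calinski_harabasz(_view(X), StatePath(labels, K=2))
        # B = 2*25 + 2*25 = 100 per axis-0; W = 4 * 0.25 = 1 -> (100/1)/(1/2)
        assert got == pytest.approx(calinski_harabasz_by_hand(X, labels))
        assert got == pytest.approx(200.0)

    def test_agrees_with_sklearn_on_random_labelings(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(120, 2))
        labels = rng.integers(0, 4, size=120)
        got = calinski_harabasz(_view(X), StatePath(labels, K=4))
        assert got == pytest.approx(calinski_harabasz_score(X, labels))

    def test_empty_state_rejected(self):
        view = _view(np.random.default_rng(12).normal(size=(10, 2)))
        path = StatePath(np.zeros(10, dtype=int), K=2)  # state 1 empty
        with pytest.raises(ValueError, match="empty state"):
            calinski_harabasz(view, path)


class TestSelection:
    def test_unsatisfiable_anchor_constraint_raises(self):
        rng = np.random.default_rng(13)
        # two far blobs; anchors on both sides can never share a state for K >= 2
        labels = np.repeat([0, 1], 100)
        X = np.where(labels[:, None] == 0, 0.0, 30.0) + rng.normal(0, 0.5, (200, 2))
        view = _view(X)
        anchors = ReferenceAnchors([("chrX", 100, "a1"), ("chrX", 150 * 200 + 100, "a2")])
        with pytest.raises(ValueError, match="anchor"):
            select_state_count(view, anchors, seed=0, k_range=range(2, 4))


class TestFragments:
    def test_run_length_merge(self):
        bins = build_bins({"chrX": 1000}, 200)
        path = StatePath(np.array([0, 0, 1, 1, 1]), K=2)
        frags = path_to_fragments(path, bins, {0: "cyan", 1: "blue"})
        expected = pd.DataFrame([
            {"chrom": "chrX", "start": 0, "end": 400, "state": "cyan"},
            {"chrom": "chrX", "start": 400, "end": 1000, "state": "blue"},
        ])
        pd.testing.assert_frame_equal(frags.df, expected)

    def test_fraction_partition_and_min_fragment(self):
        bins = build_bins({"chrX": 2000}, 200)
        path = StatePath(np.array([0, 1, 0, 0, 1, 1, 1, 0, 1, 0]), K=2)
        frags = path_to_fragments(path, bins, {0: "cyan", 1: "blue"})
        s = frags.summary()
        assert s["genome_fraction"].sum() == pytest.approx(1.0)
        assert s.loc["cyan", "min_size"] == 200  # one bin = 0.2 kb
        # concatenating fragments reproduces the path
        rebuilt = np.empty(10, dtype=object)
        for r in frags.df.itertuples(index=False):
            rebuilt[r.start // 200:r.end // 200] = r.state
        assert [{"cyan": 0, "blue": 1}[x] for x in rebuilt] == path.states.tolist()

    def test_missing_bins_leave_gaps(self):
        bins = build_bins({"chrX": 1000}, 200)
        path = StatePath(np.array([0, -1, -1, 1, 1]), K=2)
        frags = path_to_fragments(path, bins, {0: "cyan", 1: "blue"})
        assert len(frags.df) == 2
        assert (frags.df["end"] - frags.df["start"]).sum() == 600


class TestNaming:
    def _setup(self):
        # bins: 0-1 cyan-like, 2-3 blue-like, 4-5 magenta-like, 6-7 green-like
        states = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        path = StatePath(states, K=4)
        # markers: panel mean highest in state 0, lowest in state 2;
        # polII higher in state 1 than state 3
        panel = np.array([2.0, 2.0, 0.2, 0.2, -2.0, -2.0, 0.0, 0.0])
        polii = np.array([1.5, 1.5, 2.5, 2.5, -2.0, -2.0, -0.5, -0.5])
        sm = _signal(np.column_stack([panel, polii]), names=["chriz", "pol2"])
        anchors = ReferenceAnchors([("chrX", 100, "a1"), ("chrX", 300, "a2")])
        return path, sm, anchors

    def test_states_named_by_anchor_and_marker_profile(self):
        path, sm, anchors = self._setup()
        names = name_states(path, anchors, sm, ["chriz", "pol2"], ["pol2"])
        assert names == {0: "cyan", 2: "magenta", 1: "blue", 3: "green"}

    def test_anchors_in_two_states_raise(self):
        path, sm, _ = self._setup()
        anchors = ReferenceAnchors([("chrX", 100, "a1"), ("chrX", 500, "a2")])
        with pytest.raises(ValueError, match="inconsistency"):
            name_states(path, anchors, sm, ["chriz", "pol2"], ["pol2"])

    def test_extraction_produces_named_sorted_fragments(self):
        path, sm, anchors = self._setup()
        frags = anchor_and_extract(path, sm.bins, anchors, sm, ["chriz", "pol2"], ["pol2"])
        assert frags.df["state"].tolist() == ["cyan", "blue", "magenta", "green"]
        assert (frags.df["end"] - frags.df["start"] == 400).all()
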