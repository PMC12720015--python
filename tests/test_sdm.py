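import numpy as np
import pytest

from consplan import sdm, synth
from consplan.grids import EnvStack, GridSpec
from consplan.sdm import (
    EnsembleSDM,
    EnsembleSDMResults,
    ModelFit,
    apply_no_dispersal,
    auc_score,
    compute_vifs,
    confusion_metrics,
    max_tss_threshold,
    sample_pseudo_absences,
    vif_select,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def auc_pair_counting(labels, scores):
    """Brute-force AUC: fraction of (pos, neg) pairs ranked correctly."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def tss_scan_oracle(scores, labels):
    """Exhaustive scan over every candidate threshold; returns max TSS."""
    u = np.unique(scores)
    cands = np.concatenate(([0.0], (u[:-1] + u[1:]) / 2, [1.0]))
    best = -np.inf
    for t in np.unique(cands):
        pred = scores >= t
        tp = np.sum(labels & pred)
        tn = np.sum(~labels & ~pred)
        tss = tp / labels.sum() + tn / (~labels).sum() - 1
        best = max(best, tss)
    return best


def vif_inverse_corr_oracle(X):
    """VIFs as the diagonal of the inverse correlation matrix."""
    R = np.corrcoef(X, rowvar=False)
    return np.diag(np.linalg.inv(R))


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

class TestMetrics:
    def test_confusion_arithmetic(self):
        labels = np.array([1] * 10 + [0] * 10, dtype=bool)
        pred = np.array([1] * 9 + [0] * 1 + [1] * 2 + [0] * 8, dtype=bool)
        sens, spec, tss = confusion_metrics(labels, pred)
        assert (sens, spec) == (0.9, 0.8)
        assert tss == pytest.approx(0.7)

    def test_auc_matches_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(8, 30)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            scores = np.round(rng.random(n), 1)  # induce ties
            assert auc_score(labels, scores) == pytest.approx(
                auc_pair_counting(labels, scores), abs=1e-8
            )

    def test_max_tss_matches_exhaustive_scan(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = rng.integers(6, 40)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            scores = np.round(rng.random(n), 2)
            t = max_tss_threshold(scores, labels)
            tss_at_t = confusion_metrics(labels, scores >= t)[2]
            assert tss_at_t == pytest.approx(tss_scan_oracle(scores, labels),
                                             abs=1e-8)

    def test_separable_scores_give_midpoint(self):
        labels = np.array([True] * 5 + [False] * 5)
        scores = np.array([0.9] * 5 + [0.1] * 5)
        assert max_tss_threshold(scores, labels) == pytest.approx(0.5)

    def test_identical_scores_return_smallest_candidate(self):
        labels = np.array([True, True, False, False])
        scores = np.full(4, 0.4)
        t = max_tss_threshold(scores, labels)
        assert t == 0.0  # TSS is 0 everywhere; smallest candidate wins

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            max_tss_threshold(np.array([0.1, 0.9]), np.array([True, True]))


# ---------------------------------------------------------------------------
# covariate screening
# ---------------------------------------------------------------------------

class TestVif:
    def test_vifs_match_inverse_correlation_oracle(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(300, 3))
        X = np.column_stack([
            base[:, 0],
            base[:, 0] * 0.7 + base[:, 1] * 0.5 + rng.normal(size=300) * 0.3,
            base[:, 1],
            base[:, 2],
            base[:, 0] * 0.3 - base[:, 2] * 0.9 + rng.normal(size=300) * 0.2,
        ])
        np.testing.assert_allclose(
            compute_vifs(X), vif_inverse_corr_oracle(X), atol=1e-8
        )

    def test_duplicate_layer_removed(self):
        grid = GridSpec(20, 20)
        rng = np.random.default_rng(3)
        a = rng.normal(size=grid.shape)
        b = rng.normal(size=grid.shape)
        stack = EnvStack(grid, {"a": a, "dup": a.copy(), "ind": b})
        kept = vif_select(stack)
        assert len(kept) == 2
        assert "ind" in kept
        assert ("a" in kept) != ("dup" in kept)

    def test_orthogonal_layers_all_retained(self):
        grid = GridSpec(30, 30)
        rng = np.random.default_rng(4)
        X, _ = np.linalg.qr(rng.normal(size=(grid.n_cells, 4)))
        stack = EnvStack(
            grid, {f"l{j}": X[:, j].reshape(grid.shape) for j in range(4)}
        )
        kept = vif_select(stack)
        assert len(kept) == 4
        vifs = compute_vifs(stack.as_matrix())
        np.testing.assert_allclose(vifs, 1.0, atol=1e-6)


class TestPseudoAbsences:
    def test_never_overlaps_presences(self):
        grid = GridSpec(10, 10)
        presences = np.arange(0, 50)
        pa = sample_pseudo_absences(grid, presences, 30, seed=0)
        assert len(np.intersect1d(pa, presences)) == 0
        assert len(np.unique(pa)) == 30

    def test_exhaustive_request_returns_complement(self):
        grid = GridSpec(5, 5)
        presences = np.arange(0, 5)
        pa = sample_pseudo_absences(grid, presences, 20, seed=0)
        assert set(pa) == set(range(5, 25))
        with pytest.raises(ValueError):
            sample_pseudo_absences(grid, presences, 21, seed=0)

    def test_sampling_is_uniform(self):
        from scipy.stats import chisquare

        grid = GridSpec(5, 5)
        presences = np.array([0])
        counts = np.zeros(25)
        for seed in range(2500):
            pa = sample_pseudo_absences(grid, presences, 4, seed=seed)
            counts[pa] += 1
        assert chisquare(counts[1:]).pvalue > 0.01


# ---------------------------------------------------------------------------
# model fitting and the ensemble
# ---------------------------------------------------------------------------

class _ConstEstimator:
    """Stub estimator returning a fixed suitability everywhere."""

    classes_ = np.array([0, 1])

    def __init__(self, p):
        self.p = p

    def predict_proba(self, X):
        return np.column_stack([np.full(len(X), 1 - self.p),
                                np.full(len(X), self.p)])


def _stub_fit(p, retained=True):
    return ModelFit(
        species_id="s", algorithm=f"const{p}", estimator=_ConstEstimator(p),
        eval_scores=np.empty(0), eval_labels=np.empty(0),
        tss=1.0 if retained else 0.0, retained=retained,
    )


def _stub_results(model, fits):
    res = EnsembleSDMResults.__new__(EnsembleSDMResults)
    res.model = model
    res.fits = fits
    res.table_X = model.stack.as_matrix()[:4]
    res.table_y = np.array([1, 1, 0, 0])
    res.table_cells = np.arange(4)
    res.seed = 0
    res.threshold = 0.5
    return res


class TestEnsemble:
    def test_requires_five_presences(self, stack30):
        with pytest.raises(ValueError, match="at least 5"):
            EnsembleSDM(np.arange(4), stack30)

    def test_single_retained_fit_is_identity(self, stack30):
        model = EnsembleSDM(np.arange(5), stack30)
        res = _stub_results(model, [_stub_fit(0.8)])
        assert np.allclose(res.predict(), 0.8)

    def test_two_constant_fits_average(self, stack30):
        model = EnsembleSDM(np.arange(5), stack30)
        res = _stub_results(model, [_stub_fit(0.2), _stub_fit(0.8)])
        assert np.allclose(res.predict(), 0.5)

    def test_non_retained_fits_excluded_from_mean(self, stack30):
        model = EnsembleSDM(np.arange(5), stack30)
        res = _stub_results(
            model, [_stub_fit(0.9), _stub_fit(0.1, retained=False)]
        )
        assert np.allclose(res.predict(), 0.9)

    def test_perfectly_separable_toy_reaches_tss_one(self):
        grid = GridSpec(20, 20)
        rng = np.random.default_rng(5)
        # two well-separated habitat blocks: +1 vs -1 with tiny jitter
        x = np.where(np.arange(grid.n_cells) < 80, 1.0, -1.0)
        x = (x + rng.normal(0, 0.01, grid.n_cells)).reshape(grid.shape)
        stack = EnvStack(grid, {"a": x, "b": rng.normal(size=grid.shape)})
        presence = np.flatnonzero(x.ravel() > 0)
        model = EnsembleSDM(presence, stack)
        res = model.fit(seed=0)
        for f in res.fits:
            assert f.auc == pytest.approx(1.0)
            assert f.tss == pytest.approx(1.0)
            assert f.retained

    def test_random_labels_give_near_zero_skill(self):
        """With labels independent of covariates, mean TSS stays near 0."""
        grid = GridSpec(50, 40)
        rng = np.random.default_rng(6)
        stack = EnvStack(
            grid, {f"l{j}": rng.normal(size=grid.shape) for j in range(3)}
        )
        tsses = []
        for seed in range(3):
            presence = np.random.default_rng(100 + seed).choice(
                grid.n_cells, size=1000, replace=False
            )
            model = EnsembleSDM(
                presence, stack, algorithms=("logistic_glm", "random_forest")
            )
            res = model.fit(seed=seed)
            tsses += [f.tss for f in res.fits]
        assert abs(np.mean(tsses)) < 0.15

    def test_ensemble_bounded_by_member_extremes(self, stack30, species30):
        occs = synth.sample_occurrences(species30, 80, seed=7)
        res = EnsembleSDM.from_occurrences(occs, stack30).fit(seed=8)
        members = np.stack(
            [f.predict(stack30.as_matrix()) for f in res.retained_fits]
        )
        ens = res.predict().ravel()
        assert np.all(ens <= members.max(axis=0) + 1e-12)
        assert np.all(ens >= members.min(axis=0) - 1e-12)

    def test_binarize_count_matches_direct_threshold(self, stack30, species30):
        occs = synth.sample_occurrences(species30, 80, seed=9)
        res = EnsembleSDM.from_occurrences(occs, stack30).fit(seed=10)
        br = res.binarize()
        suit = res.predict()
        assert br.c == int((suit >= res.threshold).sum())

    def test_raising_threshold_never_increases_c(self, stack30, species30):
        occs = synth.sample_occurrences(species30, 80, seed=11)
        res = EnsembleSDM.from_occurrences(occs, stack30).fit(seed=12)
        suit = res.predict()
        counts = [(suit >= t).sum() for t in (0.2, 0.4, 0.6, 0.8)]
        assert counts == sorted(counts, reverse=True)

    def test_unmodelled_species_flagged(self, stack30):
        model = EnsembleSDM(np.arange(5), stack30)
        res = _stub_results(model, [_stub_fit(0.5, retained=False)])
        assert res.is_unmodelled
        with pytest.raises(sdm.UnmodelledSpeciesError):
            res.predict()


class TestProjection:
    def test_identical_future_reproduces_current(self, stack30, species30):
        occs = synth.sample_occurrences(species30, 80, seed=13)
        res = EnsembleSDM.from_occurrences(occs, stack30).fit(seed=14)
        same = stack30.copy(scenario="future_mean")
        fut = res.project_future(same)
        np.testing.assert_array_equal(fut.mask, res.binarize().mask)

    def test_no_dispersal_always_subset(self, stack30, species30):
        occs = synth.sample_occurrences(species30, 80, seed=15)
        res = EnsembleSDM.from_occurrences(occs, stack30).fit(seed=16)
        reps, mean = synth.make_future_replicates(stack30, 3, 1.0, 0.3, seed=17)
        cur = res.binarize()
        fut = res.project_future(reps, no_dispersal=True, current=cur)
        assert np.all(fut.mask <= cur.mask)

    def test_huge_shift_causes_local_extinction(self, stack30, species30):
        occs = synth.sample_occurrences(species30, 80, seed=18)
        res = EnsembleSDM.from_occurrences(occs, stack30).fit(seed=19)
        _, mean = synth.make_future_replicates(stack30, 2, -50.0, 0.0, seed=20)
        fut = res.project_future(mean, no_dispersal=True)
        assert fut.c == 0

    def test_grid_mismatch_rejected(self, stack30, species30):
        occs = synth.sample_occurrences(species30, 80, seed=21)
        res = EnsembleSDM.from_occurrences(occs, stack30).fit(seed=22)
        other = synth.generate_env_stack(GridSpec(10, 10), 6, 2.0, seed=23)
        with pytest.raises(ValueError):
            res.predict(other)

    def test_apply_no_dispersal_is_intersection(self, grid30, range_factory):
        cur = range_factory(grid30, [0, 1, 2, 3])
        fut = range_factory(grid30, [2, 3, 4, 5], scenario="future")
        out = apply_no_dispersal(cur, fut)
        assert set(np.flatnonzero(out.mask.ravel())) == {2, 3}
        assert out.scenario == "future"
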