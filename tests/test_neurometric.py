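"""Unit and property tests for preprocessing, slope maps, cluster permutation,
CI matching, and response relocking."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_epochs
from veplink import neurometric as nm, synth
from veplink.neurometric import (
    SlopeMap,
    cluster_permutation,
    fit_slope_map,
    fit_slope_maps_by_subject,
    match_behavioral_ci,
    preprocess_epochs,
    relock_to_response,
)
from veplink.psychometrics import DPrimeRegression


def _noise_epochs(rng, n_trials=60, n_channels=8, n_times=40, **kw):
    return make_epochs(rng.normal(size=(n_trials, n_channels, n_times)), **kw)


class TestPreprocess:
    def test_average_reference_zero_mean(self):
        rng = np.random.default_rng(0)
        ep = _noise_epochs(rng)
        out = preprocess_epochs(ep, zscore=False, rectify=False)
        assert np.max(np.abs(out.data.mean(axis=1))) < 1e-12

    def test_zscore_pooled_moments(self):
        rng = np.random.default_rng(1)
        ep = _noise_epochs(rng)
        out = preprocess_epochs(ep, reference=False, rectify=False)
        assert out.data.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.data.std() == pytest.approx(1.0, abs=1e-12)

    def test_zscore_is_per_subject(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(40, 4, 10))
        data[20:] *= 7.0  # second subject much larger scale
        trials = pd.DataFrame(
            dict(
                subject=np.repeat([0, 1], 20),
                jitter_deg=np.resize(synth.DEFAULT_JITTER_LEVELS, 40),
            )
        )
        ep = make_epochs(data, trials=trials)
        out = preprocess_epochs(ep, reference=False, rectify=False)
        for s in (0, 1):
            block = out.data[trials["subject"].to_numpy() == s]
            assert block.std() == pytest.approx(1.0, abs=1e-12)

    def test_rectify_nonnegative_idempotent(self):
        rng = np.random.default_rng(3)
        ep = _noise_epochs(rng)
        out = preprocess_epochs(ep)
        assert np.all(out.data >= 0)
        again = preprocess_epochs(out, reference=False, zscore=False)
        assert np.array_equal(out.data, again.data)

    def test_zero_variance_error(self):
        ep = make_epochs(np.zeros((10, 4, 5)))
        with pytest.raises(ValueError, match="variance"):
            preprocess_epochs(ep)

    def test_order_reference_before_zscore(self):
        rng = np.random.default_rng(4)
        ep = _noise_epochs(rng)
        out = preprocess_epochs(ep, rectify=False)
        # referencing happened before z-scoring: cross-channel mean is a
        # constant 0 divided by the pooled SD, still 0
        assert np.max(np.abs(out.data.mean(axis=1))) < 1e-12


class TestFitSlopeMap:
    def test_exact_linear_data(self):
        levels = np.asarray(synth.DEFAULT_JITTER_LEVELS)
        x = np.log(np.resize(levels, 120))
        data = np.broadcast_to((2.0 - 0.3 * x)[:, None, None], (120, 5, 9)).copy()
        ep = make_epochs(data)
        ep.trials["jitter_deg"] = np.resize(levels, 120)
        slopes = fit_slope_map(ep)
        assert np.allclose(slopes, -0.3, atol=1e-12)

    def test_vectorized_matches_loop_ols(self):
        rng = np.random.default_rng(5)
        levels = np.asarray(synth.DEFAULT_JITTER_LEVELS)
        data = rng.normal(size=(48, 5, 7))
        ep = make_epochs(data)
        ep.trials["jitter_deg"] = np.resize(levels, 48)
        slopes = fit_slope_map(ep)
        x = np.log(ep.trials["jitter_deg"].to_numpy())
        X = np.column_stack([np.ones_like(x), x])
        for c in range(5):
            for t in range(7):
                beta = np.linalg.lstsq(X, data[:, c, t], rcond=None)[0]
                assert slopes[c, t] == pytest.approx(beta[1], abs=1e-10)

    def test_raw_jitter_predictor(self):
        levels = np.asarray(synth.DEFAULT_JITTER_LEVELS)
        x = np.resize(levels, 120)
        data = np.broadcast_to((1.0 + 0.02 * x)[:, None, None], (120, 3, 4)).copy()
        ep = make_epochs(data)
        ep.trials["jitter_deg"] = x
        slopes = fit_slope_map(ep, predictor="jitter")
        assert np.allclose(slopes, 0.02, atol=1e-12)

    def test_single_level_error(self):
        ep = make_epochs(np.random.default_rng(0).normal(size=(12, 3, 4)))
        ep.trials["jitter_deg"] = 13.8
        with pytest.raises(ValueError, match="level"):
            fit_slope_map(ep)

    def test_null_slopes_center_on_zero(self):
        rng = np.random.default_rng(6)
        ep = _noise_epochs(rng, n_trials=200)
        slopes = fit_slope_map(ep)
        assert abs(slopes.mean()) < 0.05


def _slope_map(slopes, montage):
    S, C, T = slopes.shape
    return SlopeMap(
        slopes=slopes,
        channels=list(montage.names),
        times_ms=np.arange(T) * 5.0,
        subjects=list(range(S)),
        predictor_desc="log_jitter",
    )


class TestClusterPermutation:
    def test_all_zero_maps_empty(self, montage16):
        rng = np.random.default_rng(7)
        slopes = rng.normal(0, 1e-12, size=(8, 16, 20))
        res = cluster_permutation(_slope_map(slopes, montage16), montage16, n_perm=100)
        # sub-threshold t everywhere -> no clusters
        assert res.clusters == [] or all(c.p_value > 0.5 for c in res.clusters)

    def test_too_few_subjects(self, montage16):
        slopes = np.zeros((4, 16, 10))
        with pytest.raises(ValueError, match="5 subjects"):
            cluster_permutation(_slope_map(slopes, montage16), montage16, n_perm=10)

    def test_planted_block_single_cluster(self, montage16):
        rng = np.random.default_rng(8)
        slopes = rng.normal(0, 0.1, size=(12, 16, 30))
        chans = synth.contiguous_channel_set(montage16, 2, 5)
        slopes[:, np.asarray(chans)[:, None], 10:20] -= 0.5
        res = cluster_permutation(_slope_map(slopes, montage16), montage16, n_perm=200, seed=1)
        sig = res.significant()
        assert len(sig) == 1
        assert sig[0].p_value <= 0.01
        planted = np.zeros((16, 30), dtype=bool)
        planted[np.asarray(chans)[:, None], 10:20] = True
        jac = (sig[0].mask & planted).sum() / (sig[0].mask | planted).sum()
        assert jac >= 0.8

    def test_doubling_perms_same_clusters(self, montage16):
        rng = np.random.default_rng(9)
        slopes = rng.normal(0, 0.1, size=(10, 16, 20))
        slopes[:, 0:3, 5:12] += 0.4
        sm = _slope_map(slopes, montage16)
        a = cluster_permutation(sm, montage16, n_perm=200, seed=2)
        b = cluster_permutation(sm, montage16, n_perm=400, seed=2)
        assert len(a.clusters) == len(b.clusters)
        for ca, cb in zip(a.clusters, b.clusters):
            assert np.array_equal(ca.mask, cb.mask)
            assert ca.mass == pytest.approx(cb.mass)

    def test_channel_reorder_equivariance(self, montage16):
        from veplink.containers import Montage

        rng = np.random.default_rng(10)
        slopes = rng.normal(0, 0.1, size=(10, 16, 20))
        slopes[:, 2:6, 8:14] -= 0.6
        perm = rng.permutation(16)
        m2 = Montage(
            names=[montage16.names[i] for i in perm],
            positions=montage16.positions[perm],
            adjacency=montage16.adjacency[np.ix_(perm, perm)],
        )
        a = cluster_permutation(_slope_map(slopes, montage16), montage16, n_perm=150, seed=3)
        b = cluster_permutation(_slope_map(slopes[:, perm, :], m2), m2, n_perm=150, seed=3)
        assert len(a.clusters) == len(b.clusters)
        masses_a = sorted(c.mass for c in a.clusters)
        masses_b = sorted(c.mass for c in b.clusters)
        assert np.allclose(masses_a, masses_b)
        # the permuted-run masks match after mapping back to original order
        inv = np.argsort(perm)
        masks_a = sorted(
            (tuple(map(tuple, np.argwhere(c.mask))) for c in a.clusters)
        )
        masks_b = sorted(
            (tuple(map(tuple, np.argwhere(c.mask[inv, :]))) for c in b.clusters)
        )
        assert masks_a == masks_b

    def test_p_superuniform_under_null(self, montage16):
        # under a sign-symmetric null the minimum cluster p is super-uniform:
        # P(min p <= 0.05) <= ~0.05 (up to MC noise)
        rng = np.random.default_rng(11)
        hits = 0
        n_rep = 60
        for r in range(n_rep):
            slopes = rng.normal(0, 1.0, size=(8, 16, 15))
            res = cluster_permutation(
                _slope_map(slopes, montage16), montage16, n_perm=200, seed=100 + r
            )
            ps = [c.p_value for c in res.clusters]
            hits += bool(ps) and min(ps) <= 0.05
        assert hits <= 10  # binomial(60, 0.05) 99.9% upper bound ~ 9.6


class TestMatchBehavioralCI:
    def _sig_result(self, montage16, slopes, **kw):
        return cluster_permutation(_slope_map(slopes, montage16), montage16, n_perm=200, **kw)

    def test_point_containment(self, montage16):
        rng = np.random.default_rng(12)
        slopes = rng.normal(0, 0.05, size=(12, 16, 20))
        slopes[:, 0:4, 5:15] -= 0.19
        sm = _slope_map(slopes, montage16)
        res = self._sig_result(montage16, slopes, seed=4)
        behav = DPrimeRegression(
            beta0=0.0, beta1=-0.19, sigma=0.05, ci95_beta1=(-0.28, -0.10), n_points=6
        )
        mask = match_behavioral_ci(res, sm, behav)
        sig = res.significant_mask()
        assert mask.point_mask.any()
        assert not np.any(mask.point_mask & ~sig)  # mask subset of clusters
        assert not np.any(mask.cluster_mask & ~sig)

    def test_mismatched_slope_excluded(self, montage16):
        rng = np.random.default_rng(13)
        slopes = rng.normal(0, 0.05, size=(12, 16, 20))
        slopes[:, 0:4, 5:15] += 0.2  # positive slope, CI negative
        sm = _slope_map(slopes, montage16)
        res = self._sig_result(montage16, slopes, seed=5)
        behav = DPrimeRegression(
            beta0=0.0, beta1=-0.19, sigma=0.05, ci95_beta1=(-0.28, -0.10), n_points=6
        )
        mask = match_behavioral_ci(res, sm, behav)
        assert res.significant()  # the cluster exists
        assert not mask.point_mask.any()  # but nothing matches the CI
        assert not mask.cluster_mask.any()

    def test_grid_mismatch_error(self, montage16):
        rng = np.random.default_rng(14)
        slopes = rng.normal(size=(8, 16, 20))
        res = self._sig_result(montage16, slopes, seed=6)
        other = _slope_map(rng.normal(size=(8, 16, 25)), montage16)
        behav = DPrimeRegression(0.0, -0.2, 0.05, (-0.3, -0.1), 6)
        with pytest.raises(ValueError, match="grid"):
            match_behavioral_ci(res, other, behav)

    def test_behavioral_ci_from_subject_list(self):
        regs = [
            DPrimeRegression(0.0, b1, 0.05, (b1 - 0.1, b1 + 0.1), 6)
            for b1 in (-0.3, -0.25, -0.35, -0.28, -0.32)
        ]
        lo, hi = nm.behavioral_slope_ci(regs)
        b1s = [r.beta1 for r in regs]
        from scipy import stats as st

        se = np.std(b1s, ddof=1) / np.sqrt(len(b1s))
        tcrit = st.t.ppf(0.975, len(b1s) - 1)
        assert lo == pytest.approx(np.mean(b1s) - tcrit * se)
        assert hi == pytest.approx(np.mean(b1s) + tcrit * se)


class TestRelock:
    def test_rt_zero_is_identity_crop(self):
        rng = np.random.default_rng(15)
        data = rng.normal(size=(10, 4, 401))  # -1000..1000 at 200 Hz
        ep = make_epochs(data, t0_ms=-1000.0)
        ep.trials["rt_ms"] = 0.0
        out = relock_to_response(ep, window_ms=(-1000.0, 0.0))
        sl = ep.time_window_slice(-1000.0, 0.0)
        assert np.array_equal(out.data, ep.data[:, :, sl])
        assert out.lock == "response"

    def test_fixed_preresponse_component_aligns_after_relock(self):
        # a bump placed rt-100 ms after stimulus onset per trial appears at a
        # fixed -100 ms latency only in the response-locked average
        rng = np.random.default_rng(16)
        fs = 200.0
        times = -200.0 + 5.0 * np.arange(281)  # -200..1200
        n_trials = 40
        rts = rng.uniform(400.0, 900.0, n_trials)
        data = rng.normal(0, 0.1, size=(n_trials, 3, len(times)))
        for i, rt in enumerate(rts):
            data[i, :, :] += 2.0 * np.exp(-((times - (rt - 100.0)) ** 2) / (2 * 15.0**2))
        ep = make_epochs(data, t0_ms=-200.0, fs_hz=fs)
        ep.trials["rt_ms"] = rts
        out = relock_to_response(ep, window_ms=(-400.0, 0.0))
        avg = out.data.mean(axis=(0, 1))
        peak_ms = out.times_ms[np.argmax(avg)]
        assert abs(peak_ms - (-100.0)) <= 5.0
        # stimulus-locked average is smeared: lower, wider peak
        stim_avg = ep.data.mean(axis=(0, 1))
        assert stim_avg.max() < avg.max() * 0.6

    def test_all_trials_dropped_error(self):
        ep = make_epochs(np.zeros((5, 3, 81)), t0_ms=-100.0)
        ep.trials["rt_ms"] = 10_000.0
        with pytest.raises(ValueError, match="no trial"):
            relock_to_response(ep, window_ms=(-200.0, 0.0))

    def test_out_of_range_trials_dropped(self):
        rng = np.random.default_rng(17)
        ep = make_epochs(rng.normal(size=(6, 3, 281)), t0_ms=-200.0)
        ep.trials["rt_ms"] = [500.0, 600.0, 5_000.0, 550.0, 700.0, 650.0]
        out = relock_to_response(ep, window_ms=(-400.0, 0.0))
        assert out.n_trials == 5

    def test_missing_rt_error(self):
        ep = make_epochs(np.zeros((5, 3, 81)))
        ep.trials.drop(columns=["rt_ms"], inplace=True)
        with pytest.raises(ValueError, match="rt_ms"):
            relock_to_response(ep)


class TestFitSlopeMapsBySubject:
    def test_stacks_per_subject(self):
        rng = np.random.default_rng(18)
        data = rng.normal(size=(48, 4, 6))
        trials = pd.DataFrame(
            dict(
                subject=np.repeat([0, 1], 24),
                jitter_deg=np.resize(synth.DEFAULT_JITTER_LEVELS, 48),
            )
        )
        ep = make_epochs(data, trials=trials)
        sm = fit_slope_maps_by_subject(ep)
        assert sm.slopes.shape == (2, 4, 6)
        first = ep.copy_with(data=data[:24], trials=trials.iloc[:24].reset_index(drop=True))
        assert np.allclose(sm.slopes[0], fit_slope_map(first))
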