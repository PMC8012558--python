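"""User-learning metrics: classDis, TTA, band power, robust Fisher score, trends."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from riembci import geometry as geo, metrics
from riembci.geometry import SPDSet
from riembci.metrics import LandmarkSet
from riembci.simulate import SimConfig, sample_spd_class_set

from conftest import random_invertible, random_spd

E = np.e


def scalar_set(values, labels=None):
    return SPDSet(np.array([[[v]] for v in values], float),
                  None if labels is None else np.array(labels))


class TestClassDis2:
    def test_identical_sets_zero(self, rng):
        mats = np.array([random_spd(rng, 3) for _ in range(5)])
        a, b = SPDSet(mats), SPDSet(mats.copy())
        assert metrics.class_dis_2(a, b) == pytest.approx(0.0, abs=1e-6)

    def test_scalar_hand_computation(self):
        # means 1 and e^2, each with Fréchet std 1 -> classDis = 2
        a = scalar_set([np.exp(-1), np.exp(1)])
        b = scalar_set([np.exp(1), np.exp(3)])
        assert metrics.class_dis_2(a, b) == pytest.approx(2.0, rel=1e-6)

    def test_monotone_in_mean_separation(self, rng):
        base = np.array([random_spd(rng, 3, 0.3) for _ in range(20)])
        a = SPDSet(base)
        target = random_spd(rng, 3)
        values = []
        for t in (0.2, 0.4, 0.6, 0.8):
            shift = geo.geodesic_point(np.eye(3), target, t)
            w = geo.sqrtm(shift)
            values.append(metrics.class_dis_2(a, SPDSet(geo.congruence(base, w))))
        assert all(x < y for x, y in zip(values, values[1:]))

    def test_zero_dispersion_warns_inf(self):
        with pytest.warns(UserWarning):
            v = metrics.class_dis_2(scalar_set([2.0]), scalar_set([5.0]))
        assert np.isinf(v)


class TestClassDisMulti:
    def test_null_case_near_zero(self):
        rng = np.random.default_rng(7)
        mats = np.array([random_spd(rng, 3, 0.3) for _ in range(300)])
        labels = np.array(list("abc") * 100)
        assert metrics.class_dis_multi(SPDSet(mats, labels=labels)) < 0.1

    def test_orders_with_two_class_version(self):
        cfg_near = SimConfig(n_channels=4, n_classes=2, class_mean_spread=0.5,
                             n_epochs_per_class=40, seed=3)
        cfg_far = SimConfig(n_channels=4, n_classes=2, class_mean_spread=2.0,
                            n_epochs_per_class=40, seed=3)
        near, _ = sample_spd_class_set(cfg_near)
        far, _ = sample_spd_class_set(cfg_far)
        assert metrics.class_dis_multi(far) > metrics.class_dis_multi(near)
        a_n, b_n = (near.subset(near.labels == c) for c in near.classes())
        a_f, b_f = (far.subset(far.labels == c) for c in far.classes())
        assert metrics.class_dis_2(a_f, b_f) > metrics.class_dis_2(a_n, b_n)

    def test_invariant_under_common_congruence(self, rng):
        covs, _ = sample_spd_class_set(SimConfig(n_channels=4, n_epochs_per_class=15, seed=5))
        w = random_invertible(rng, 4)
        before = metrics.class_dis_multi(covs)
        after = metrics.class_dis_multi(SPDSet(geo.congruence(covs.mats, w), labels=covs.labels))
        assert after == pytest.approx(before, abs=1e-8)

    def test_scale_free(self, rng):
        covs, _ = sample_spd_class_set(SimConfig(n_channels=4, n_epochs_per_class=10, seed=6))
        before = metrics.class_dis_multi(covs)
        after = metrics.class_dis_multi(SPDSet(3.7 * covs.mats, labels=covs.labels))
        assert after == pytest.approx(before, abs=1e-8)


class TestLandmarks:
    def test_single_sample_classes(self, rng):
        m1, m2 = random_spd(rng, 3), random_spd(rng, 3)
        lm = metrics.compute_landmarks(SPDSet(np.array([m1, m2]), labels=np.array(["a", "b"])))
        np.testing.assert_allclose(lm.class_means[0], m1, atol=1e-9)
        np.testing.assert_allclose(lm.class_stds, 0.0, atol=1e-9)

    def test_congruence_equivariance(self, rng):
        covs, _ = sample_spd_class_set(SimConfig(n_channels=4, n_epochs_per_class=12, seed=8))
        w = random_invertible(rng, 4)
        lm0 = metrics.compute_landmarks(covs)
        lm1 = metrics.compute_landmarks(SPDSet(geo.congruence(covs.mats, w), labels=covs.labels))
        for m0, m1 in zip(lm0.class_means, lm1.class_means):
            np.testing.assert_allclose(m1, geo.congruence(m0, w), atol=1e-5)
        np.testing.assert_allclose(lm1.class_stds, lm0.class_stds, atol=1e-7)

    def test_global_mean_is_pooled_karcher_mean(self, rng):
        covs, _ = sample_spd_class_set(SimConfig(n_channels=4, n_epochs_per_class=10, seed=9))
        lm = metrics.compute_landmarks(covs)
        np.testing.assert_allclose(lm.global_mean, geo.karcher_mean(covs.mats), atol=1e-7)


class TestTTA:
    def _scalar_landmarks(self, means, stds, gmean, gstd):
        return LandmarkSet(
            class_ids=np.array(["a", "b"])[: len(means)],
            class_means=np.array([[[m]] for m in means], float),
            class_stds=np.array(stds, float),
            global_mean=np.array([[gmean]], float),
            global_std=float(gstd),
        )

    def test_identical_landmarks_zero(self, rng):
        covs, _ = sample_spd_class_set(SimConfig(n_channels=4, n_epochs_per_class=10, seed=10))
        lm = metrics.compute_landmarks(covs)
        assert metrics.tta(lm, lm) == pytest.approx(0.0, abs=1e-10)

    def test_scalar_hand_computation(self):
        train = self._scalar_landmarks([1.0, E**2], [1.0, 1.0], E, 1.0)
        test = self._scalar_landmarks([E, E**3], [0.5, 0.5], E**2, 2.0)
        # each class mean moved one log-unit, global mean moved one log-unit,
        # all train stds 1 -> TTA = (1 + 1 + 1)/3 = 1
        assert metrics.tta(train, test) == pytest.approx(1.0, rel=1e-10)

    def test_monotone_decrease_toward_train(self, rng):
        covs, _ = sample_spd_class_set(SimConfig(n_channels=4, n_epochs_per_class=20, seed=11))
        train_lm = metrics.compute_landmarks(covs)
        far = [geo.congruence(m, np.diag([2.0, 1.0, 0.7, 1.4])) for m in train_lm.class_means]
        values = []
        for t in (0.0, 0.3, 0.6, 0.9):
            test_lm = LandmarkSet(
                class_ids=train_lm.class_ids,
                class_means=np.array(
                    [geo.geodesic_point(f, m, t) for f, m in zip(far, train_lm.class_means)]
                ),
                class_stds=train_lm.class_stds,
                global_mean=geo.geodesic_point(
                    geo.congruence(train_lm.global_mean, np.diag([2.0, 1.0, 0.7, 1.4])),
                    train_lm.global_mean,
                    t,
                ),
                global_std=train_lm.global_std,
            )
            values.append(metrics.tta(train_lm, test_lm))
        assert all(x > y for x, y in zip(values, values[1:]))

    def test_zero_train_std_rejected(self):
        lm = self._scalar_landmarks([1.0, 2.0], [0.0, 1.0], 1.5, 1.0)
        with pytest.raises(ValueError, match="class"):
            metrics.tta(lm, lm)

    def test_invariant_under_common_congruence(self, rng):
        tr, _ = sample_spd_class_set(SimConfig(n_channels=4, n_epochs_per_class=12, seed=12))
        te, _ = sample_spd_class_set(SimConfig(n_channels=4, n_epochs_per_class=12, seed=13))
        w = random_invertible(rng, 4)
        t0 = metrics.tta(metrics.compute_landmarks(tr), metrics.compute_landmarks(te))
        tr_w = SPDSet(geo.congruence(tr.mats, w), labels=tr.labels)
        te_w = SPDSet(geo.congruence(te.mats, w), labels=te.labels)
        t1 = metrics.tta(metrics.compute_landmarks(tr_w), metrics.compute_landmarks(te_w))
        assert t1 == pytest.approx(t0, abs=1e-8)


class TestBandPower:
    FS = 256.0

    def test_alpha_tone_dominates(self):
        t = np.arange(int(4 * self.FS)) / self.FS
        epoch = np.sin(2 * np.pi * 10.0 * t)[None, None, :]
        table = metrics.band_power(epoch, self.FS)
        p = table.set_index("band")["power"]
        assert p["alpha"] / max(p["low_beta"], p["high_beta"]) > 10

    def test_white_noise_flat_psd(self, rng):
        epoch = rng.standard_normal((1, 1, 10_000))
        table = metrics.band_power(epoch, self.FS)
        p = table.set_index("band")["power"]
        # per-Hz PSD roughly equal across bands for white noise
        assert p["alpha"] == pytest.approx(p["high_beta"], rel=0.25)

    def test_zero_signal_zero_power(self):
        table = metrics.band_power(np.zeros((1, 2, 512)), self.FS)
        assert (table["power"] == 0).all()

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            metrics.band_power(np.zeros((1, 1, 512)), 50.0, {"bad": (8.0, 30.0)})


class TestRobustFisherScore:
    def _table(self, powers_by_class, run="R1", channel=0, band="alpha"):
        rows = []
        for label, powers in powers_by_class.items():
            for i, p in enumerate(powers):
                rows.append({"epoch": i, "channel": channel, "band": band,
                             "power": p, "label": label, "run_id": run})
        return pd.DataFrame(rows)

    def test_equal_medians_zero(self):
        table = self._table({"a": [1.0, 1.0, 2.0, 0.0], "b": [1.0, 3.0, 1.0, -1.0]})
        fs = metrics.robust_fisher_score(table, "alpha")
        assert fs["R1"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computation(self):
        # medians 1 and 3, MADs 1 and 1, m0 = 2 -> FS = (1+1)/(1+1) = 1
        table = self._table({"a": [0.0, 1.0, 2.0], "b": [2.0, 3.0, 4.0]})
        fs = metrics.robust_fisher_score(table, "alpha")
        assert fs["R1"] == pytest.approx(1.0, rel=1e-12)

    def test_location_invariance(self):
        t1 = self._table({"a": [0.0, 1.0, 2.0], "b": [2.0, 3.0, 4.0]})
        t2 = t1.copy()
        t2["power"] += 17.3
        v1 = metrics.robust_fisher_score(t1, "alpha")["R1"]
        v2 = metrics.robust_fisher_score(t2, "alpha")["R1"]
        assert v2 == pytest.approx(v1, rel=1e-12)

    def test_literal_sum_center_flag(self):
        table = self._table({"a": [0.0, 1.0, 2.0], "b": [2.0, 3.0, 4.0]})
        # m0 = 1 + 3 = 4 -> ((1-4)^2 + (3-4)^2)/2 = 5
        fs = metrics.robust_fisher_score(table, "alpha", m0="sum")
        assert fs["R1"] == pytest.approx(5.0, rel=1e-12)

    def test_zero_mads_warn_inf(self):
        table = self._table({"a": [1.0, 1.0, 1.0], "b": [3.0, 3.0, 3.0]})
        with pytest.warns(UserWarning):
            fs = metrics.robust_fisher_score(table, "alpha")
        assert np.isinf(fs["R1"])


class TestChanceLevel:
    def test_asymptotic_limit(self):
        assert metrics.chance_level_upper(100_000, 4) == pytest.approx(25.0, abs=0.5)

    def test_monotone_decreasing_in_trials(self):
        values = [metrics.chance_level_upper(n, 4) for n in (5, 10, 20, 40, 160)]
        assert all(x >= y for x, y in zip(values, values[1:]))
        assert values[0] > values[-1]

    def test_matches_inverse_cdf_brute_force(self):
        n, p, alpha = 40, 0.25, 0.05
        cdf = np.cumsum([scipy.stats.binom.pmf(k, n, p) for k in range(n + 1)])
        k_star = next(k for k in range(n + 1) if cdf[k] >= 1 - alpha / 2)
        assert metrics.chance_level_upper(10, 4, alpha) == pytest.approx(100 * k_star / n)


class TestLearningTrend:
    def test_perfect_increase(self):
        r, p = metrics.learning_trend([1, 2, 3, 4], [1, 2, 3, 4])
        assert r == pytest.approx(1.0)

    def test_orthogonal_by_symmetry(self):
        r, _ = metrics.learning_trend([1.0, 2.0, 1.0], [1, 2, 3])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_formula(self, rng):
        x = rng.standard_normal(15)
        idx = np.arange(15.0)
        r, _ = metrics.learning_trend(x, idx)
        num = np.sum((x - x.mean()) * (idx - idx.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((idx - idx.mean()) ** 2))
        assert r == pytest.approx(num / den, abs=1e-10)

    def test_constant_values_nan(self):
        with pytest.warns(UserWarning):
            r, p = metrics.learning_trend([2.0, 2.0, 2.0], [1, 2, 3])
        assert np.isnan(r) and np.isnan(p)

    def test_too_few_runs_rejected(self):
        with pytest.raises(ValueError):
            metrics.learning_trend([1.0, 2.0], [1, 2])
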