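import numpy as np
import pytest

from duotox import qsar
from duotox.errors import UsageError
from duotox.fields import FieldConfig
from duotox.synthetic import (
    SyntheticSpec,
    generate_molecule_set,
    plant_activities,
    recovery_field_config,
)


def random_regression(rng, n=15, p=6, noise=0.0):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


class TestFitPLS:
    def test_exact_linear_single_column(self, rng):
        X = np.column_stack([np.arange(10.0), np.zeros(10)])
        y = 3.0 * X[:, 0] + 1.0
        model = qsar.fit_pls(X, y, 1)
        stats = qsar.fit_statistics(model, X, y)
        assert stats.r2 == pytest.approx(1.0, abs=1e-12)

    def test_full_rank_equals_ols_oracle(self, rng):
        # 20 random instances: PLS with n_components = p matches the
        # closed-form least-squares fit
        for _ in range(20):
            X, y = random_regression(rng, n=20, p=5, noise=0.3)
            model = qsar.fit_pls(X, y, 5)
            Xc = np.column_stack([np.ones(len(y)), X])
            beta = np.linalg.lstsq(Xc, y, rcond=None)[0]
            y_ols = Xc @ beta
            assert np.max(np.abs(model.predict(X) - y_ols)) < 1e-8

    def test_matches_sklearn_nipals(self, rng):
        # independent cross-check against scikit-learn's NIPALS for a
        # reduced-rank fit (scale=False matches our centering-only scheme)
        from sklearn.cross_decomposition import PLSRegression

        X, y = random_regression(rng, n=25, p=8, noise=0.5)
        for a in (1, 2, 3):
            ours = qsar.fit_pls(X, y, a)
            ref = PLSRegression(n_components=a, scale=False).fit(X, y.reshape(-1, 1))
            assert np.allclose(ours.predict(X), ref.predict(X).ravel(), atol=1e-8)

    def test_constant_y(self):
        X = np.random.default_rng(0).normal(size=(8, 3))
        y = np.full(8, 2.5)
        with pytest.warns(UserWarning):
            model = qsar.fit_pls(X, y, 2)
        assert np.array_equal(model.coef, np.zeros(3))
        stats = qsar.fit_statistics(model, X, y)
        assert stats.r2 == 0.0

    def test_rank_deficiency_truncates_with_warning(self, rng):
        X = np.tile(rng.normal(size=(10, 1)), (1, 4))  # rank 1
        y = X[:, 0] * 2.0
        with pytest.warns(UserWarning, match="rank exhausted"):
            model = qsar.fit_pls(X, y, 3)
        assert model.n_components == 1

    def test_too_few_observations(self):
        with pytest.raises(UsageError):
            qsar.fit_pls(np.ones((3, 2)), np.ones(3), 3)


class TestLooQ2:
    def test_noiseless_planted(self, recovery_activities):
        X = recovery_activities.descriptors.X
        q2, _ = qsar.loo_q2(X, recovery_activities.z, X.shape[1])
        assert q2 > 0.99

    def test_permuted_response_q2_nonpositive_in_mean(self, recovery_activities, rng):
        X = recovery_activities.descriptors.X
        y = recovery_activities.z
        q2s = []
        for _ in range(50):
            q2, _ = qsar.loo_q2(X, rng.permutation(y), 5)
            q2s.append(q2)
        assert np.mean(q2s) < 0.05

    def test_three_point_perfect_line(self):
        X = np.array([[0.0], [1.0], [2.0]])
        y = np.array([1.0, 3.0, 5.0])
        q2, csdep = qsar.loo_q2(X, y, 1)
        assert q2 == pytest.approx(1.0, abs=1e-12)
        assert csdep == pytest.approx(0.0, abs=1e-9)

    def test_q2_not_above_r2(self, rng):
        for _ in range(10):
            X, y = random_regression(rng, n=15, p=4, noise=1.0)
            a = 3
            q2, _ = qsar.loo_q2(X, y, a)
            model = qsar.fit_pls(X, y, a)
            r2 = qsar.fit_statistics(model, X, y).r2
            assert q2 <= r2 + 1e-12

    def test_component_scan_tie_break(self, rng):
        X, y = random_regression(rng, n=20, p=5, noise=0.1)
        best, rows = qsar.component_scan(X, y, max_components=5)
        q2s = [r["q2"] for r in rows]
        assert rows[best - 1]["q2"] == max(q2s)
        for r in rows:
            if r["q2"] == rows[best - 1]["q2"]:
                assert best <= r["n_components"]

    def test_component_scan_sep_criterion(self, rng):
        X, y = random_regression(rng, n=20, p=5, noise=0.1)
        best, rows = qsar.component_scan(X, y, max_components=5, criterion="sep")
        assert rows[best - 1]["csdep"] == min(r["csdep"] for r in rows)


class TestExternalValidation:
    def make_model(self, rng):
        X, y = random_regression(rng, n=20, p=4)
        return qsar.fit_pls(X, y, 4), X, y

    def test_perfect_predictions(self, rng):
        model, X, y = self.make_model(rng)
        r2_pred, sep = qsar.external_validation(model, X[:5], model.predict(X[:5]), float(y.mean()))
        assert r2_pred == pytest.approx(1.0, abs=1e-9)
        assert sep == pytest.approx(0.0, abs=1e-9)

    def test_training_mean_prediction_gives_zero(self):
        # a model that predicts the training mean for every row
        model = qsar.PLSModel(
            n_components=1,
            x_mean=np.zeros(2),
            y_mean=1.5,
            coef=np.zeros(2),
            x_weights=np.zeros((2, 1)),
            x_loadings=np.zeros((2, 1)),
            y_loadings=np.zeros(1),
            scores=np.zeros((4, 1)),
        )
        y_test = np.array([0.0, 1.0, 2.0, 4.0])
        r2_pred, _ = qsar.external_validation(model, np.zeros((4, 2)), y_test, 1.5)
        assert r2_pred == pytest.approx(0.0, abs=1e-12)

    def test_four_row_hand_arithmetic(self):
        # hand oracle: y_test=[1,2,3,4], y_hat=[1.5,2,2.5,5], mean=2
        # SD = 1+0+1+4 = 6 ; PRESS = .25+0+.25+1 = 1.5
        # r2_pred = (6-1.5)/6 = 0.75 ; SEP = sqrt(1.5/4)
        model = qsar.PLSModel(
            n_components=1,
            x_mean=np.zeros(1),
            y_mean=0.0,
            coef=np.ones(1),
            x_weights=np.ones((1, 1)),
            x_loadings=np.ones((1, 1)),
            y_loadings=np.ones(1),
            scores=np.zeros((4, 1)),
        )
        X_test = np.array([[1.5], [2.0], [2.5], [5.0]])
        y_test = np.array([1.0, 2.0, 3.0, 4.0])
        r2_pred, sep = qsar.external_validation(model, X_test, y_test, 2.0)
        assert r2_pred == pytest.approx(0.75, abs=1e-12)
        assert sep == pytest.approx(np.sqrt(1.5 / 4), abs=1e-12)

    def test_sd_zero_flagged(self, rng):
        model, X, y = self.make_model(rng)
        r2_pred, _ = qsar.external_validation(model, X[:3], np.full(3, float(y.mean())), float(y.mean()))
        assert np.isnan(r2_pred)


class TestContributions:
    def test_single_field_gets_everything(self, rng):
        X = rng.normal(size=(10, 6))
        col_field = np.array(["S", "S", "E", "E", "H", "H"], dtype=object)
        model = qsar.fit_pls(X, X[:, 0], 1)
        model.coef = np.array([1.0, 2.0, 0.0, 0.0, 0.0, 0.0])
        contrib = qsar.field_contributions(model, X, col_field)
        assert contrib["S"] == pytest.approx(100.0)
        assert contrib["E"] == contrib["H"] == 0.0

    def test_symmetric_split(self):
        X = np.ones((5, 2)) * np.arange(5)[:, None]  # equal column SDs
        col_field = np.array(["S", "E"], dtype=object)
        model = qsar.fit_pls(X, X[:, 0], 1)
        model.coef = np.array([0.5, -0.5])
        contrib = qsar.field_contributions(model, X, col_field)
        assert contrib["S"] == pytest.approx(50.0)
        assert contrib["E"] == pytest.approx(50.0)

    def test_sums_to_100(self, recovery_activities):
        X = recovery_activities.descriptors.X
        model = qsar.fit_pls(X, recovery_activities.z, 5)
        contrib = qsar.field_contributions(model, X, recovery_activities.descriptors.column_field)
        assert sum(contrib.values()) == pytest.approx(100.0, abs=0.01)

    def test_planted_ratio_recovered(self, synth_molecules, synth_spec):
        # plant signal mass in S and H at a known 3:1 contribution ratio
        fc = recovery_field_config()
        base = plant_activities(synth_molecules, synth_spec, fc)
        desc = base.descriptors
        kept_s = desc.blocks["S"].kept_columns
        kept_h = desc.blocks["H"].kept_columns
        sd_s = desc.blocks["S"].values[:, kept_s[1]].std()
        sd_h = desc.blocks["H"].values[:, kept_h[1]].std()
        # coefficient * column SD mass ratio 3:1
        spec = SyntheticSpec(
            n_molecules=40,
            seed=7,
            planted_coefficients={
                "S": {int(kept_s[1]): 3.0 / sd_s},
                "H": {int(kept_h[1]): 1.0 / sd_h},
            },
        )
        act = plant_activities(synth_molecules, spec, fc)
        X = act.descriptors.X
        model = qsar.fit_pls(X, act.z, X.shape[1])
        contrib = qsar.field_contributions(model, X, act.descriptors.column_field)
        assert contrib["S"] == pytest.approx(75.0, abs=5.0)
        assert contrib["H"] == pytest.approx(25.0, abs=5.0)


@pytest.fixture(scope="module")
def lean_planted(synth_molecules, synth_spec):
    # 20-column identifiable regime keeps LOO honest at few components
    return plant_activities(synth_molecules, synth_spec, FieldConfig(spacing=7.0, margin=1.0))


class TestScrambling:
    def test_level_zero_is_baseline(self, lean_planted):
        X, y = lean_planted.descriptors.X, lean_planted.z
        rep = qsar.progressive_scrambling(
            X, y, 3, levels=(0.0, 0.5, 1.0), seed=0, n_repeats=2
        )
        level0 = [r for r in rep.levels if r["level"] == 0.0][0]
        assert level0["q2"] == rep.baseline_q2
        assert level0["r2yy"] == 1.0

    def test_full_scrambling_destroys_q2(self, lean_planted, rng):
        X, y = lean_planted.descriptors.X, lean_planted.z
        q2s = []
        for seed in range(20):
            rep = qsar.progressive_scrambling(
                X, y, 3, levels=(0.2, 0.6, 1.0), seed=seed, n_repeats=2
            )
            q2s.append([r for r in rep.levels if r["level"] == 1.0][0]["q2"])
        assert np.mean(q2s) <= 0.05

    def test_slope_near_one_and_stable(self, lean_planted):
        X, y = lean_planted.descriptors.X, lean_planted.z
        slopes = []
        for seed in range(20):
            rep = qsar.progressive_scrambling(
                X, y, 3, levels=(0.1, 0.3, 0.5, 0.7, 0.9, 1.0), seed=seed, n_repeats=3
            )
            slopes.append(rep.slope)
        slopes = np.array(slopes)
        assert abs(np.mean(slopes) - 1.0) < 0.4
        assert slopes.std() < 0.2

    def test_too_few_levels(self, lean_planted):
        with pytest.raises(UsageError):
            qsar.progressive_scrambling(lean_planted.descriptors.X, lean_planted.z, 2, levels=(0.5, 1.0))


class TestContours:
    def test_all_positive_coefficients(self, recovery_activities):
        desc = recovery_activities.descriptors
        model = qsar.fit_pls(desc.X, recovery_activities.z, 3)
        model.coef = np.abs(model.coef) + 0.1
        contours = qsar.extract_contours(model, desc)
        assert any(contours.favored[f].sum() > 0 for f in "SEHDA")
        assert all(contours.disfavored[f].sum() == 0 for f in "SEHDA")

    def test_symmetric_coefficients_both_masks(self, recovery_activities):
        desc = recovery_activities.descriptors
        model = qsar.fit_pls(desc.X, recovery_activities.z, 3)
        cols = desc.columns_of("S")
        model.coef[:] = 0.0
        model.coef[cols] = np.resize([1.0, -1.0], cols.size)
        contours = qsar.extract_contours(model, desc)
        assert contours.favored["S"].sum() > 0
        assert contours.disfavored["S"].sum() > 0

    def test_masks_disjoint(self, recovery_activities):
        desc = recovery_activities.descriptors
        model = qsar.fit_pls(desc.X, recovery_activities.z, 5)
        contours = qsar.extract_contours(model, desc)
        for f in "SEHDA":
            assert not np.any(contours.favored[f] & contours.disfavored[f])

    def test_planted_hotspot_in_favored_mask(self, synth_molecules):
        fc = recovery_field_config()
        base = plant_activities(synth_molecules, SyntheticSpec(n_molecules=40, seed=7), fc)
        kept = base.descriptors.blocks["S"].kept_columns
        hotspot = int(kept[2])
        spec = SyntheticSpec(
            n_molecules=40, seed=7, planted_coefficients={"S": {hotspot: 2.0}}
        )
        act = plant_activities(synth_molecules, spec, fc)
        desc = act.descriptors
        model = qsar.fit_pls(desc.X, act.z, desc.X.shape[1])
        contours = qsar.extract_contours(model, desc)
        # exact recovery concentrates the positive StDev*Coeff at the hotspot
        assert contours.favored["S"][hotspot]
        assert int(np.argmax(contours.stdev_coeff["S"])) == hotspot

    def test_percentile_validation(self, recovery_activities):
        desc = recovery_activities.descriptors
        model = qsar.fit_pls(desc.X, recovery_activities.z, 3)
        with pytest.raises(UsageError):
            qsar.extract_contours(model, desc, favored_pct=20.0, disfavored_pct=80.0)
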