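"""Four-population death gating: thresholds, gate rays, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from organodeath import (
    DeathGater,
    classify_nuclei,
    fit_gate_lines,
    fit_viable_thresholds,
    simulate_nuclei,
    summarize_death,
    validate_positive_control,
)


def records(caspase, pi):
    return pd.DataFrame({"mean_caspase": caspase, "mean_pi": pi})


def brute_force_classify(c, p, tc, tp, theta_lo, theta_hi):
    """Independent point-in-region oracle for one nucleus.

    Mirrors the geometric definition directly: viable below both
    thresholds, otherwise the (clipped) angle about the anchor decides
    the sector.
    """
    if c <= tc and p <= tp:
        return "viable"
    dc = max(c - tc, 0.0)
    dp = max(p - tp, 0.0)
    alpha = np.degrees(np.arctan2(dp, dc))
    if alpha < theta_lo:
        return "apoptotic"
    if alpha > theta_hi:
        return "necrotic"
    return "late_apoptotic"


class TestViableThresholds:
    def test_hand_arithmetic(self):
        """{1,2,3} has mean 2, sample SD 1 -> threshold 4."""
        tc, tp = fit_viable_thresholds(records([1, 2, 3], [2, 4, 6]))
        assert tc == pytest.approx(4.0)
        assert tp == pytest.approx(4.0 + 2 * 2.0)

    def test_zero_variance_gives_the_constant(self):
        tc, tp = fit_viable_thresholds(records([7, 7, 7], [3, 3, 3]))
        assert (tc, tp) == (7.0, 3.0)

    def test_fewer_than_two_nuclei_rejected(self):
        with pytest.raises(ValueError):
            fit_viable_thresholds(records([1.0], [1.0]))

    def test_normal_tail_product(self):
        """10,000 viable nuclei with independent normal channels: the
        fraction below both mean+2SD thresholds is Phi(2)^2 +/- 0.01."""
        df = simulate_nuclei(10_000, {"viable": 1.0}, seed=5)
        model = DeathGater().fit(df)
        frac = (model.predict(df) == "viable").mean()
        assert frac == pytest.approx(norm.cdf(2.0) ** 2, abs=0.01)

    def test_log_scale_thresholds(self):
        df = records([10.0, 100.0, 1000.0], [10.0, 100.0, 1000.0])
        model = DeathGater(scale="log10").fit(df)
        assert model.t_caspase_ == pytest.approx(2.0 + 2 * 1.0)  # log10 mean 2, SD 1


class TestClassification:
    @pytest.fixture()
    def model(self):
        m = DeathGater()
        # controls clustered near (10, 10) -> thresholds just above
        rng = np.random.default_rng(0)
        m.fit(records(rng.normal(10, 1, 100), rng.normal(10, 1, 100)))
        return m

    def test_origin_is_viable(self, model):
        assert model.predict([[0.0, 0.0]])[0] == "viable"

    def test_axis_aligned_extremes(self, model):
        tc, tp = model.thresholds()
        assert model.predict([[10 * tc, 0.0]])[0] == "apoptotic"
        assert model.predict([[0.0, 10 * tp]])[0] == "necrotic"
        assert model.predict([[10 * tc, 10 * tp]])[0] == "late_apoptotic"

    def test_matches_brute_force_oracle_exactly(self, model, rng):
        """1000 random intensity points: vectorised classification agrees
        with the scalar point-in-region oracle with zero mismatches."""
        tc, tp = model.thresholds()
        c = rng.uniform(0, 4 * tc, 1000)
        p = rng.uniform(0, 4 * tp, 1000)
        got = model.predict(np.column_stack([c, p]))
        expected = [
            brute_force_classify(ci, pi, tc, tp, model.theta_necrotic_, model.theta_apoptotic_)
            for ci, pi in zip(c, p)
        ]
        assert (got == np.asarray(expected, dtype=object)).all()

    def test_partition_exhaustive_and_exclusive(self, model, rng):
        labels = model.predict(
            np.column_stack([rng.uniform(0, 100, 500), rng.uniform(0, 100, 500)])
        )
        assert set(labels) <= {"viable", "apoptotic", "necrotic", "late_apoptotic"}
        assert not pd.isna(labels).any()

    def test_threshold_monotonicity(self, rng):
        """Raising either threshold never decreases the viable count."""
        xy = np.column_stack([rng.uniform(0, 100, 800), rng.uniform(0, 100, 800)])
        base = DeathGater.from_dict(
            dict(t_caspase=40, t_pi=40, theta_apoptotic=60, theta_necrotic=30)
        )
        n0 = (base.predict(xy) == "viable").sum()
        for bump in ((10, 0), (0, 10), (25, 25)):
            m = DeathGater.from_dict(
                dict(
                    t_caspase=40 + bump[0],
                    t_pi=40 + bump[1],
                    theta_apoptotic=60,
                    theta_necrotic=30,
                )
            )
            assert (m.predict(xy) == "viable").sum() >= n0

    def test_unfitted_model_raises(self):
        with pytest.raises(Exception):
            DeathGater().predict([[1.0, 1.0]])

    def test_invalid_angles_rejected(self):
        with pytest.raises(ValueError):
            DeathGater(theta_apoptotic=30, theta_necrotic=60).fit(
                records([1, 2, 3], [1, 2, 3])
            )

    def test_log_scale_shift_invariance(self):
        """On log scale, multiplying all intensities by a constant shifts
        the thresholds but leaves classifications unchanged."""
        rng = np.random.default_rng(3)
        day0 = records(rng.lognormal(3, 0.3, 400), rng.lognormal(3, 0.3, 400))
        pts = records(rng.lognormal(4, 1.0, 300), rng.lognormal(4, 1.0, 300))
        m1 = DeathGater(scale="log10").fit(day0)
        m2 = DeathGater(scale="log10").fit(day0 * 37.0)
        np.testing.assert_array_equal(m1.predict(pts), m2.predict(pts * 37.0))


class TestGateCalibration:
    def test_default_angles_passthrough(self):
        m = DeathGater().fit(records([1, 2, 3], [1, 2, 3]))
        assert m.theta_apoptotic_ == 60.0
        assert m.theta_necrotic_ == 30.0

    def test_calibrated_on_separated_modes(self):
        """Day-10 controls with three well-separated death modes: the
        calibrated rays classify >= 95% of apoptotic and necrotic cells
        correctly."""
        day0 = simulate_nuclei(2000, {"viable": 1.0}, seed=1)
        day10 = simulate_nuclei(
            3000,
            {"viable": 0.4, "apoptotic": 0.2, "necrotic": 0.2, "late_apoptotic": 0.2},
            seed=2,
        )
        m = DeathGater(calibrate_angles=True).fit(day0, day10)
        pred = m.predict(day10)
        for mode in ("apoptotic", "necrotic"):
            sel = day10["death_mode"] == mode
            assert (pred[sel.to_numpy()] == mode).mean() >= 0.95

    def test_rotation_equivariance(self):
        """Rotating all dead points by +10 deg about the anchor shifts
        both calibrated angles by +10 deg (within 1 deg)."""
        rng = np.random.default_rng(6)
        day0 = records(rng.normal(50, 5, 500), rng.normal(50, 5, 500))
        m0 = DeathGater().fit(day0)
        tc, tp = m0.thresholds()
        # dead points in an angular band about the anchor
        alpha = np.radians(rng.uniform(10, 60, 800))
        radius = rng.uniform(50, 200, 800)
        pts = records(tc + radius * np.cos(alpha), tp + radius * np.sin(alpha))
        m1 = fit_gate_lines(pts, (tc, tp))
        rotated = records(
            tc + radius * np.cos(alpha + np.radians(10)),
            tp + radius * np.sin(alpha + np.radians(10)),
        )
        m2 = fit_gate_lines(rotated, (tc, tp))
        assert m2.theta_necrotic_ - m1.theta_necrotic_ == pytest.approx(10.0, abs=1.0)
        assert m2.theta_apoptotic_ - m1.theta_apoptotic_ == pytest.approx(10.0, abs=1.0)

    def test_no_dead_cells_warns_and_keeps_defaults(self):
        day0 = simulate_nuclei(500, {"viable": 1.0}, seed=9)
        with pytest.warns(UserWarning):
            m = DeathGater(calibrate_angles=True).fit(day0, records([1.0, 2.0], [1.0, 2.0]))
        assert m.theta_apoptotic_ == 60.0

    def test_recovery_rate_at_default_separation(self):
        """Total misclassification vs ground truth < 5% over 2000 nuclei
        with the default >= 5x low/high mode separation, using the full
        calibration flow (thresholds on day 0, gate rays on day 10)."""
        day0 = simulate_nuclei(2000, {"viable": 1.0}, seed=31)
        mix = {"viable": 0.55, "apoptotic": 0.15, "necrotic": 0.15, "late_apoptotic": 0.15}
        day10 = simulate_nuclei(2000, mix, seed=33)
        mixed = simulate_nuclei(2000, mix, seed=32)
        m = DeathGater(calibrate_angles=True).fit(day0, day10)
        pred = m.predict(mixed)
        err = (pred != mixed["death_mode"].to_numpy()).mean()
        assert err < 0.05


class TestSummaries:
    def fitted(self):
        return DeathGater().fit(records([40, 50, 60], [40, 50, 60]))

    def test_empty_well_all_zero(self):
        counts = summarize_death(records([], []), self.fitted(), well_id="C3")
        assert counts.total == 0
        assert counts.as_dict()["frac_viable"] == 0.0

    def test_counts_sum_and_fractions(self):
        df = simulate_nuclei(
            500, {"viable": 0.5, "apoptotic": 0.5}, seed=12
        )
        counts = summarize_death(df, self.fitted())
        assert counts.total == 500
        assert sum(counts.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_order_invariance(self):
        df = simulate_nuclei(300, {"viable": 0.6, "necrotic": 0.4}, seed=13)
        a = summarize_death(df, self.fitted())
        b = summarize_death(df.sample(frac=1.0, random_state=0), self.fitted())
        assert a == b

    def test_generator_labels_recovered(self):
        """10 viable + 5 apoptotic synthetic nuclei at generator defaults
        gate to at least (9, 4) with total 15."""
        df = pd.concat(
            [
                simulate_nuclei(10, {"viable": 1.0}, seed=1),
                simulate_nuclei(5, {"apoptotic": 1.0}, seed=2),
            ],
            ignore_index=True,
        )
        model = DeathGater().fit(simulate_nuclei(1000, {"viable": 1.0}, seed=3))
        counts = summarize_death(df, model)
        assert counts.total == 15
        assert counts.n_viable >= 9
        assert counts.n_apoptotic >= 4


class TestPositiveControl:
    def setup_method(self):
        self.model = DeathGater().fit(simulate_nuclei(1000, {"viable": 1.0}, seed=4))

    def test_clear_kill_passes(self):
        stauro = {
            "S1": simulate_nuclei(200, {"late_apoptotic": 0.9, "viable": 0.1}, seed=5)
        }
        untreated = {"U1": simulate_nuclei(200, {"viable": 0.9, "apoptotic": 0.1}, seed=6)}
        ok, fracs = validate_positive_control(stauro, untreated, self.model)
        assert ok
        assert fracs["staurosporine"] > fracs["untreated"] + 0.2

    def test_identical_distributions_fail(self):
        a = {"S1": simulate_nuclei(300, {"viable": 0.8, "apoptotic": 0.2}, seed=7)}
        b = {"U1": simulate_nuclei(300, {"viable": 0.8, "apoptotic": 0.2}, seed=7)}
        ok, _ = validate_positive_control(a, b, self.model)
        assert not ok

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            validate_positive_control({}, {"U1": records([1], [1])}, self.model)


@settings(deadline=None, max_examples=30)
@given(
    tc=st.floats(1.0, 100.0),
    tp=st.floats(1.0, 100.0),
    c=st.floats(0.0, 500.0),
    p=st.floats(0.0, 500.0),
)
def test_partition_property(tc, tp, c, p):
    """Every intensity point gets exactly one class, and the viable rule
    is exactly 'at or below both thresholds'."""
    m = DeathGater.from_dict(
        dict(t_caspase=tc, t_pi=tp, theta_apoptotic=60.0, theta_necrotic=30.0)
    )
    label = m.predict([[c, p]])[0]
    if c <= tc and p <= tp:
        assert label == "viable"
    else:
        assert label in {"apoptotic", "necrotic", "late_apoptotic"}
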