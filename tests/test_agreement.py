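"""Agreement statistics against closed forms and independent oracles."""

import numpy as np
import pytest
from scipy import stats

from neuromapopt.agreement import (
    SessionPair,
    bland_altman,
    build_report,
    linear_fit,
    repeated_measures_corr,
    within_threshold_fraction,
)


def _pairs(pid, x, y):
    return [
        SessionPair(p, f"{p}S{i}", float(a), float(b))
        for i, (p, a, b) in enumerate(zip(pid, x, y))
    ]


def _random_dataset(rng, n_patients=None):
    k = n_patients or int(rng.integers(3, 9))
    pid, x, y = [], [], []
    for p in range(k):
        n = int(rng.integers(2, 6))
        off = rng.normal(0.0, 10.0)
        xs = rng.normal(90.0, 8.0, n)
        ys = 0.7 * xs + off + rng.normal(0.0, 3.0, n)
        pid += [f"P{p}"] * n
        x += list(xs)
        y += list(ys)
    return _pairs(pid, x, y)


def rmcorr_normal_equations(pairs):
    """Independent oracle: shared-slope ANCOVA via an explicit design matrix."""
    kept = [p for p in pairs if p.both_valid]
    pid = np.asarray([p.patient_id for p in kept])
    x = np.asarray([p.mapopt_prx for p in kept])
    y = np.asarray([p.mapopt_p2p1 for p in kept])
    subjects = np.unique(pid)
    dummies = (pid[:, None] == subjects[None, :]).astype(float)
    X_full = np.column_stack([dummies, x])
    beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    ss_err = float(np.sum((y - X_full @ beta) ** 2))
    beta0, *_ = np.linalg.lstsq(dummies, y, rcond=None)
    ss_reduced = float(np.sum((y - dummies @ beta0) ** 2))
    ss_measure = ss_reduced - ss_err
    r = np.sign(beta[-1]) * np.sqrt(ss_measure / (ss_measure + ss_err))
    return float(r), len(kept) - len(subjects) - 1


class TestRmcorr:
    def test_perfect_within_patient_linearity(self):
        pid = ["A", "A", "A", "B", "B", "B"]
        x = [80.0, 90.0, 100.0, 82.0, 88.0, 94.0]
        y_up = [v + 5 if p == "A" else v - 12 for p, v in zip(pid, x)]
        res = repeated_measures_corr(_pairs(pid, x, y_up))
        assert res.r == pytest.approx(1.0, abs=1e-12)
        y_dn = [-v + 5 if p == "A" else -v - 12 for p, v in zip(pid, x)]
        res = repeated_measures_corr(_pairs(pid, x, y_dn))
        assert res.r == pytest.approx(-1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pairs = _random_dataset(rng)
            mine = repeated_measures_corr(pairs)
            r_oracle, df_oracle = rmcorr_normal_equations(pairs)
            assert mine.r == pytest.approx(r_oracle, abs=1e-8)
            assert mine.df == df_oracle

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(1)
        for _ in range(5):
            pairs = _random_dataset(rng)
            mine = repeated_measures_corr(pairs)
            df = pd.DataFrame(
                {
                    "subject": [p.patient_id for p in pairs],
                    "x": [p.mapopt_prx for p in pairs],
                    "y": [p.mapopt_p2p1 for p in pairs],
                }
            )
            ref = pg.rm_corr(df, x="x", y="y", subject="subject")
            assert mine.r == pytest.approx(float(ref.r.iloc[0]), abs=1e-8)
            assert mine.df == int(ref.dof.iloc[0])
            assert mine.p_value == pytest.approx(float(ref.pval.iloc[0]), rel=1e-6)

    def test_single_patient_reduces_to_pearson(self):
        rng = np.random.default_rng(2)
        x = rng.normal(90.0, 8.0, 10)
        y = 0.5 * x + rng.normal(0.0, 2.0, 10)
        res = repeated_measures_corr(_pairs(["A"] * 10, x, y))
        r_ref, _ = stats.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-12)

    def test_zero_within_patient_variance_raises(self):
        pairs = _pairs(["A", "A", "B", "B"], [90, 90, 85, 85], [88, 89, 84, 86])
        with pytest.raises(ValueError, match="variance"):
            repeated_measures_corr(pairs)


class TestBlandAltman:
    def test_closed_form(self):
        pairs = _pairs(["A", "B", "C"], [90.0, 92.0, 94.0], [90.0, 90.0, 90.0])
        ba = bland_altman(pairs)
        assert ba.bias == pytest.approx(2.0)
        assert ba.sd_diff == pytest.approx(2.0)
        assert ba.loa_low == pytest.approx(-1.92)
        assert ba.loa_high == pytest.approx(5.92)

    def test_identical_methods(self):
        pairs = _pairs(["A", "B"], [90.0, 95.0], [90.0, 95.0])
        ba = bland_altman(pairs)
        assert ba.bias == 0.0 and ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_antisymmetry_under_method_swap(self):
        rng = np.random.default_rng(3)
        pairs = _random_dataset(rng)
        swapped = [
            SessionPair(p.patient_id, p.session_id, p.mapopt_p2p1, p.mapopt_prx)
            for p in pairs
        ]
        ba, ba_swap = bland_altman(pairs), bland_altman(swapped)
        assert ba_swap.bias == pytest.approx(-ba.bias, abs=1e-12)
        assert ba_swap.loa_low == pytest.approx(-ba.loa_high, abs=1e-12)
        assert ba_swap.loa_high == pytest.approx(-ba.loa_low, abs=1e-12)
        r = repeated_measures_corr(pairs).r
        r_swap = repeated_measures_corr(swapped).r
        assert r_swap == pytest.approx(r, abs=1e-12)

    def test_sampling_recovery_of_planted_offset(self):
        # 268 pairs with planted +2 mmHg offset and diff SD 3
        rng = np.random.default_rng(4)
        x = rng.normal(90.0, 8.0, 268)
        y = x - 2.0 + rng.normal(0.0, 3.0, 268)
        ba = bland_altman(_pairs([f"P{i}" for i in range(268)], x, y))
        assert 1.5 <= ba.bias <= 2.5
        width = ba.loa_high - ba.loa_low
        assert width == pytest.approx(2 * 1.96 * 3.0, rel=0.15)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(_pairs(["A"], [90.0], [88.0]))


class TestThresholdFraction:
    def test_examples(self):
        pairs = _pairs(list("ABCD"), [91, 85, 93, 97], [90, 90, 90, 90])
        assert within_threshold_fraction(pairs, 6.0) == pytest.approx(0.75)
        same = _pairs(list("AB"), [90, 92], [90, 92])
        assert within_threshold_fraction(same, 6.0) == 1.0

    def test_boundary_is_inside(self):
        pairs = _pairs(["A"], [96.0], [90.0])  # diff exactly 6
        assert within_threshold_fraction(pairs, 6.0) == 1.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        pairs = _random_dataset(rng)
        fracs = [within_threshold_fraction(pairs, t) for t in (0.0, 2.0, 6.0, 20.0)]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))


class TestLinearFit:
    def test_exact_lines(self):
        pairs = _pairs(list("ABC"), [80.0, 90.0, 100.0], [80.0, 90.0, 100.0])
        assert linear_fit(pairs) == pytest.approx((1.0, 0.0))
        x = np.array([80.0, 90.0, 100.0])
        pairs = _pairs(list("ABC"), x, 0.9 * x + 11.0)
        slope, intercept = linear_fit(pairs)
        assert slope == pytest.approx(0.9, abs=1e-10)
        assert intercept == pytest.approx(11.0, abs=1e-8)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(6)
        x = rng.normal(90.0, 8.0, 40)
        y = rng.normal(0.9, 0.1) * x + rng.normal(0.0, 3.0, 40)
        slope, intercept = linear_fit(_pairs([f"P{i}" for i in range(40)], x, y))
        A = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert slope == pytest.approx(beta[0], abs=1e-10)
        assert intercept == pytest.approx(beta[1], abs=1e-8)

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError):
            linear_fit(_pairs(["A", "B"], [90.0, 90.0], [88.0, 89.0]))


class TestBuildReport:
    def test_single_pair_contract(self):
        report = build_report(_pairs(["A"], [90.0], [88.0]))
        assert report.bland is None and report.rmcorr is None
        assert report.n_sessions == 1
        assert report.fraction_within_threshold == 1.0

    def test_invalid_pairs_excluded(self):
        pairs = _pairs(list("ABC"), [90.0, 92.0, 94.0], [88.0, 90.0, 92.0])
        pairs.append(SessionPair("D", "DS0", None, 90.0))
        report = build_report(pairs)
        assert report.n_sessions == 3
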