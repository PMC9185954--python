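import math

import numpy as np
import pandas as pd
import pytest

from myotubekit.errors import InvalidParameterError
from myotubekit.reliability import (
    MDD_FACTOR,
    RatingsMatrix,
    icc,
    mdd,
    reliability_result,
    reliability_table,
    sem_from_icc,
)

from oracles import anova_icc_oneway, anova_icc_twoway


@pytest.fixture
def integer_ratings():
    """6 subjects x 2 raters, small integers, hand-checkable."""
    return RatingsMatrix(
        np.array([[9, 2], [6, 1], [8, 4], [7, 1], [10, 5], [6, 2]], dtype=float),
        parameter="demo",
    )


class TestICC:
    def test_perfect_agreement_all_forms_one(self):
        values = np.tile(np.array([[3.0], [7.0], [11.0], [2.0]]), (1, 2))
        ratings = RatingsMatrix(values)
        for form in ("oneway", "agreement", "consistency"):
            assert icc(ratings, form).estimate == pytest.approx(1.0)

    def test_constant_offset_consistency_vs_agreement(self):
        base = np.array([3.0, 7.0, 11.0, 2.0, 9.0, 5.0])
        ratings = RatingsMatrix(np.column_stack([base, base + 4.0]))
        assert icc(ratings, "consistency").estimate == pytest.approx(1.0)
        assert icc(ratings, "agreement").estimate < 1.0

    def test_matches_hand_anova_oracle(self, integer_ratings):
        got1 = icc(integer_ratings, "oneway").estimate
        gotA = icc(integer_ratings, "agreement").estimate
        gotC = icc(integer_ratings, "consistency").estimate
        exp1 = anova_icc_oneway(integer_ratings.values)
        expA, expC = anova_icc_twoway(integer_ratings.values)
        assert got1 == pytest.approx(exp1, abs=1e-12)
        assert gotA == pytest.approx(expA, abs=1e-12)
        assert gotC == pytest.approx(expC, abs=1e-12)

    def test_matches_pingouin(self, integer_ratings):
        """Independent library cross-check of estimates and CIs."""
        pingouin = pytest.importorskip("pingouin")
        n, k = integer_ratings.values.shape
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "ratings": integer_ratings.values.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            df, targets="targets", raters="raters", ratings="ratings"
        ).set_index("Type")
        for form, ref_type in [
            ("oneway", "ICC(1,1)"),
            ("agreement", "ICC(A,1)"),
            ("consistency", "ICC(C,1)"),
        ]:
            res = icc(integer_ratings, form)
            assert res.estimate == pytest.approx(ref.loc[ref_type, "ICC"], abs=1e-9)
            lo, hi = ref.loc[ref_type, "CI95"]
            assert res.ci_low == pytest.approx(lo, abs=0.02)
            assert res.ci_high == pytest.approx(hi, abs=0.02)

    def test_ci_brackets_estimate(self, integer_ratings):
        for form in ("oneway", "agreement", "consistency"):
            res = icc(integer_ratings, form)
            assert res.ci_low <= res.estimate <= res.ci_high

    def test_consistency_invariant_under_affine_rescale(self, integer_ratings):
        base = icc(integer_ratings, "consistency").estimate
        scaled = RatingsMatrix(integer_ratings.values * 3.7 + 11.0)
        assert icc(scaled, "consistency").estimate == pytest.approx(base, abs=1e-10)

    def test_all_forms_invariant_under_subject_reordering(self, integer_ratings, rng):
        perm = rng.permutation(integer_ratings.n_subjects)
        shuffled = RatingsMatrix(integer_ratings.values[perm])
        for form in ("oneway", "agreement", "consistency"):
            assert icc(shuffled, form).estimate == pytest.approx(
                icc(integer_ratings, form).estimate, abs=1e-12
            )

    def test_zero_between_subject_variance_warns(self):
        ratings = RatingsMatrix(np.array([[5.0, 6.0], [5.0, 6.0], [5.0, 6.0]]))
        with pytest.warns(UserWarning, match="degenerate"):
            res = icc(ratings, "oneway")
        assert res.estimate <= 0  # no subject signal

    def test_oneway_recovers_variance_ratio(self):
        """ICC(1) converges to sigma_s^2 / (sigma_s^2 + sigma_e^2)."""
        rng = np.random.default_rng(777)
        sigma_s, sigma_e = 2.0, 1.0
        expected = sigma_s**2 / (sigma_s**2 + sigma_e**2)
        n, reps = 200, 500
        estimates = np.empty(reps)
        for i in range(reps):
            subjects = rng.normal(0, sigma_s, size=(n, 1))
            values = 10.0 + subjects + rng.normal(0, sigma_e, size=(n, 2))
            estimates[i] = icc(RatingsMatrix(values), "oneway").estimate
        assert abs(estimates.mean() - expected) < 0.05


class TestSEMAndMDD:
    def test_perfect_agreement_zero_sem(self):
        values = np.tile(np.array([[3.0], [7.0], [11.0]]), (1, 2))
        ratings = RatingsMatrix(values)
        assert sem_from_icc(ratings, 1.0) == pytest.approx(0.0)

    def test_icc_zero_gives_pooled_sd_pct(self, integer_ratings):
        expected = 100.0 * integer_ratings.pooled_sd / integer_ratings.grand_mean
        assert sem_from_icc(integer_ratings, 0.0) == pytest.approx(expected)

    def test_error_ms_variant(self, integer_ratings):
        sem = sem_from_icc(integer_ratings, 0.5, method="error_ms")
        assert sem > 0

    def test_icc_above_one_rejected(self, integer_ratings):
        with pytest.raises(InvalidParameterError):
            sem_from_icc(integer_ratings, 1.5)

    def test_mdd_formula(self):
        assert mdd(0.0) == 0.0
        assert mdd(10.0) == pytest.approx(10.0 * 1.96 * math.sqrt(2))
        assert mdd(12.0) == pytest.approx(33.26, abs=0.01)

    def test_mdd_sem_ratio_exact(self, rng):
        for sem in rng.uniform(0.01, 60.0, size=20):
            assert mdd(sem) / sem == pytest.approx(MDD_FACTOR, abs=1e-12)

    def test_negative_sem_rejected(self):
        with pytest.raises(InvalidParameterError):
            mdd(-1.0)

    def test_sem_recovers_generating_error_sd(self):
        """SEM estimates the simulated measurement-error SD."""
        rng = np.random.default_rng(4242)
        sigma_s, sigma_e, mean = 3.0, 0.8, 20.0
        n, reps = 50, 500
        sems = np.empty(reps)
        for i in range(reps):
            subjects = rng.normal(0, sigma_s, size=(n, 1))
            values = mean + subjects + rng.normal(0, sigma_e, size=(n, 2))
            ratings = RatingsMatrix(values)
            est = icc(ratings, "oneway").estimate
            sems[i] = sem_from_icc(ratings, est) / 100.0 * ratings.grand_mean
        assert abs(sems.mean() - sigma_e) / sigma_e < 0.15


class TestReliabilityTable:
    @staticmethod
    def _rater_frames(rng, n_sets=8):
        truth = pd.DataFrame(
            {
                "image_set": [f"img{i}" for i in range(n_sets)],
                "fusion_index": rng.uniform(0.2, 0.8, n_sets),
                "n_clusters": rng.integers(2, 15, n_sets).astype(float),
            }
        )
        frames = []
        for _ in range(2):
            noisy = truth.copy()
            noisy["fusion_index"] += rng.normal(0, 0.02, n_sets)
            noisy["n_clusters"] += rng.normal(0, 0.5, n_sets)
            frames.append(noisy)
        return frames

    def test_table_shape_and_columns(self, rng):
        table = reliability_table(self._rater_frames(rng))
        assert list(table["parameter"]) == ["fusion_index", "n_clusters"]
        for col in ("ICC1", "ICCA1", "ICCC1", "SEM_pct", "MDD_pct"):
            assert col in table.columns
        assert (table["MDD_pct"] / table["SEM_pct"]).round(9).eq(round(MDD_FACTOR, 9)).all()

    def test_alignment_on_image_set_id(self, rng):
        a, b = self._rater_frames(rng)
        b = b.sample(frac=1.0, random_state=0)  # shuffled row order
        t1 = reliability_table([a, b])
        t2 = reliability_table([a, b.sort_values("image_set")])
        pd.testing.assert_frame_equal(t1, t2)

    def test_requires_two_raters(self, rng):
        with pytest.raises(ValueError):
            reliability_table(self._rater_frames(rng)[:1])

    def test_full_result_record(self, integer_ratings):
        res = reliability_result(integer_ratings)
        assert res.mdd_pct == pytest.approx(res.sem_pct * MDD_FACTOR)
        assert res.icc1.estimate <= 1.0
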