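import numpy as np
import pytest

from amyseg.metrics import MetricsReport, dice, evaluate_cohort, icc, jaccard, pearson
from amyseg.volumes import LabelMap, ValidationError


def lm(mask):
    return LabelMap(np.asarray(mask, dtype=np.int16))


def random_pair(rng, shape=(6, 6, 6)):
    return (lm(rng.integers(0, 2, shape)), lm(rng.integers(0, 2, shape)))


class TestDiceJaccard:
    def test_identical_nonempty(self, rng):
        a = lm(rng.integers(0, 2, (5, 5, 5)))
        assert dice(a, a, 1) == 1.0
        assert jaccard(a, a, 1) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4, 4))
        b = np.zeros((4, 4, 4))
        a[0, 0, 0] = 1
        b[1, 1, 1] = 1
        assert dice(lm(a), lm(b), 1) == 0.0
        assert jaccard(lm(a), lm(b), 1) == 0.0

    def test_counting_oracle(self):
        # |A| = 4, |B| = 4, |A∩B| = 3 -> dice 0.75; |A∪B| = 5 -> jaccard 0.6
        a = np.zeros((4, 4, 4))
        b = np.zeros((4, 4, 4))
        a.flat[:4] = 1
        b.flat[1:5] = 1
        assert dice(lm(a), lm(b), 1) == pytest.approx(0.75)
        assert jaccard(lm(a), lm(b), 1) == pytest.approx(0.6)

    def test_both_empty_convention(self):
        a = lm(np.zeros((3, 3, 3)))
        assert dice(a, a, 1) == 1.0
        assert jaccard(a, a, 1) == 1.0

    def test_symmetry_and_identity_sweep(self, rng):
        for _ in range(200):
            a, b = random_pair(rng)
            d = dice(a, b, 1)
            j = jaccard(a, b, 1)
            assert d == dice(b, a, 1)
            assert j == jaccard(b, a, 1)
            assert abs(j - d / (2.0 - d)) < 1e-12

    def test_grid_mismatch(self):
        with pytest.raises(ValidationError):
            dice(lm(np.zeros((3, 3, 3))), lm(np.zeros((4, 4, 4))), 1)


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert pearson(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 10.0])
        expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_scipy_oracle_sweep(self, rng):
        from scipy import stats

        for _ in range(100):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            assert pearson(x, y) == pytest.approx(stats.pearsonr(x, y)[0], abs=1e-10)

    def test_zero_variance(self):
        with pytest.raises(ValidationError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _icc_oracle(table, kind):
    """Textbook two-way ANOVA mean squares, computed independently."""
    r = np.asarray(table, dtype=float)
    n, k = r.shape
    grand = r.mean()
    msr = k * np.sum((r.mean(axis=1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((r.mean(axis=0) - grand) ** 2) / (k - 1)
    mse = (np.sum((r - grand) ** 2) - (n - 1) * msr - (k - 1) * msc) / ((n - 1) * (k - 1))
    if kind == "consistency":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


class TestICC:
    def test_identical_raters(self):
        t = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [5.0, 5.0]])
        assert icc(t, "consistency") == pytest.approx(1.0)
        assert icc(t, "absolute") == pytest.approx(1.0)

    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 7.0])
        t = np.column_stack([x, x + 2.0])
        assert icc(t, "consistency") == pytest.approx(1.0)
        assert icc(t, "absolute") < 1.0
        assert icc(t, "absolute") == pytest.approx(_icc_oracle(t, "absolute"), abs=1e-10)

    def test_hand_computed_table(self):
        t = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0], [4.0, 5.0]])
        assert icc(t, "consistency") == pytest.approx(_icc_oracle(t, "consistency"), abs=1e-10)
        assert icc(t, "absolute") == pytest.approx(_icc_oracle(t, "absolute"), abs=1e-10)

    def test_pingouin_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(size=8)
        y = x + rng.normal(scale=0.3, size=8) + 0.5
        df = pd.DataFrame({
            "subject": list(range(8)) * 2,
            "rater": ["a"] * 8 + ["b"] * 8,
            "score": np.concatenate([x, y]),
        })
        res = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="score").set_index("Type")
        table = np.column_stack([x, y])
        assert icc(table, "consistency") == pytest.approx(res.loc["ICC(C,1)", "ICC"], abs=1e-8)
        assert icc(table, "absolute") == pytest.approx(res.loc["ICC(A,1)", "ICC"], abs=1e-8)

    def test_consistency_ge_absolute_when_msc_ge_mse(self, rng):
        for _ in range(100):
            x = rng.normal(size=6)
            t = np.column_stack([x, x + rng.normal(scale=0.2, size=6) + 1.0])
            # systematic offset makes MSC >= MSE virtually always; assert on those
            n, k = t.shape
            grand = t.mean()
            msc = n * np.sum((t.mean(axis=0) - grand) ** 2) / (k - 1)
            mse_num = np.sum((t - grand) ** 2)
            msr = k * np.sum((t.mean(axis=1) - grand) ** 2) / (n - 1)
            mse = (mse_num - (n - 1) * msr - (k - 1) * msc) / ((n - 1) * (k - 1))
            if msc >= mse:
                assert icc(t, "consistency") >= icc(t, "absolute") - 1e-12

    def test_degenerate(self):
        t = np.ones((4, 2))
        with pytest.raises(ValidationError):
            icc(t, "consistency")


class TestEvaluateCohort:
    def _cohort(self, rng, n=5):
        segs = {}
        for i in range(n):
            labels = np.zeros((8, 8, 8), dtype=np.int16)
            labels[1:3 + i % 2, 1:4, 1:4] = 1
            labels[5:7, 4:6 + i % 2, 2:5] = 2
            segs[f"s{i}"] = LabelMap(labels, spacing=(1.0, 1.0, 1.2))
        return segs

    def test_identical_cohorts_all_ones(self, rng):
        ref = self._cohort(rng)
        rep = evaluate_cohort(ref, ref)
        assert (rep.per_subject["dice"] == 1.0).all()
        assert (rep.per_subject["jaccard"] == 1.0).all()
        for entry in rep.cohort.values():
            assert entry["pearson_r"] == pytest.approx(1.0)
            assert entry["icc_consistency"] == pytest.approx(1.0)
            assert entry["icc_absolute"] == pytest.approx(1.0)

    def test_row_identity_and_volumes(self, rng):
        ref = self._cohort(rng)
        auto = {k: LabelMap(np.roll(v.labels, 1, axis=0), v.spacing) for k, v in ref.items()}
        rep = evaluate_cohort(auto, ref)
        for _, row in rep.per_subject.iterrows():
            d = row["dice"]
            assert abs(row["jaccard"] - d / (2.0 - d)) < 1e-12

    def test_volume_in_mm3(self):
        labels = np.zeros((10, 10, 10), dtype=np.int16)
        labels.flat[:100] = 1
        m = LabelMap(labels, spacing=(1.0, 1.0, 1.2))
        assert m.volume_mm3(1) == pytest.approx(120.0)

    def test_id_mismatch(self, rng):
        ref = self._cohort(rng)
        auto = dict(list(ref.items())[:-1])
        with pytest.raises(ValidationError, match="s4"):
            evaluate_cohort(auto, ref)

    def test_report_writers(self, tmp_path, rng):
        ref = self._cohort(rng)
        rep = evaluate_cohort(ref, ref)
        rep.to_csv(tmp_path / "r.csv")
        rep.to_json(tmp_path / "r.json")
        import json

        import pandas as pd

        df = pd.read_csv(tmp_path / "r.csv")
        assert set(df.columns) >= {"subject", "structure", "dice", "jaccard"}
        payload = json.loads((tmp_path / "r.json").read_text())
        assert "cohort" in payload and "per_subject" in payload
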