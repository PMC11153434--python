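"""ICC(2,1): ANOVA oracle agreement, categories, designs, summaries."""

import numpy as np
import pandas as pd
import pytest

from conseg.reliability import (
    DesignSpec,
    categorize_icc,
    icc_a1,
    run_design,
    stable_features,
    summarize,
)

from oracles import oracle_icc_a1


class TestIccA1:
    def test_perfect_agreement(self):
        res = icc_a1(np.array([[1, 1], [2, 2], [3, 3.0]]))
        assert res.icc == pytest.approx(1.0)
        assert res.category == "excellent"

    def test_hand_anova_example(self):
        res = icc_a1(np.array([[1, 2], [3, 4], [5, 6.0]]))
        assert res.icc == pytest.approx(8.0 / 9.0, abs=1e-12)

    def test_matches_loop_oracle_on_random_matrices(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(2, 31))
            k = int(rng.integers(2, 6))
            m = rng.normal(size=(n, k)) * rng.uniform(0.1, 10) + rng.uniform(-5, 5)
            assert icc_a1(m).icc == pytest.approx(oracle_icc_a1(m), abs=1e-10)

    def test_matches_pingouin_icc2(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        for _ in range(25):
            n, k = int(rng.integers(4, 15)), int(rng.integers(2, 5))
            m = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            df = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(n), k),
                    "rater": np.tile(np.arange(k), n),
                    "score": m.ravel(),
                }
            )
            ref = pingouin.intraclass_corr(
                data=df, targets="subject", raters="rater", ratings="score"
            )
            # single-measure absolute agreement: labelled ICC2 or ICC(A,1)
            sel = ref["Type"].isin(["ICC2", "ICC(A,1)"])
            icc2 = float(ref.loc[sel, "ICC"].iloc[0])
            assert icc_a1(m).icc == pytest.approx(icc2, abs=1e-8)

    def test_constant_matrix_flagged_invalid(self):
        res = icc_a1(np.full((4, 3), 2.5))
        assert not res.valid
        assert np.isnan(res.icc)

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(8, 3))
        base = icc_a1(m).icc
        assert icc_a1(m + 17.3).icc == pytest.approx(base, abs=1e-10)
        assert icc_a1(m * 4.2).icc == pytest.approx(base, abs=1e-10)

    def test_nonfinite_rejected(self):
        m = np.array([[1, 2], [np.nan, 4.0]])
        with pytest.raises(ValueError):
            icc_a1(m)


class TestCategorize:
    @pytest.mark.parametrize(
        "icc,expected",
        [
            (0.95, "excellent"),
            (0.9, "excellent"),
            (0.8999, "good"),
            (0.75, "good"),
            (0.74999, "moderate"),
            (0.5, "moderate"),
            (0.49999, "poor"),
            (0.0, "poor"),
        ],
    )
    def test_printed_partition(self, icc, expected):
        assert categorize_icc(icc) == expected

    def test_negative_uses_absolute_value(self):
        assert categorize_icc(-0.3) == "poor"
        assert categorize_icc(-0.95) == "excellent"
        res = icc_a1(np.array([[1, 5], [2, 1], [3, 4.0], [4, 0.0]]))
        if res.icc < 0:
            assert res.negative_flag


def _feature_table(rng, n_cases=13, features=("f1", "f2", "f3")):
    """Synthetic feature table covering all methods, masks and GT."""
    rows = []
    base = {f: rng.uniform(1, 10, size=n_cases) for f in features}
    for method in ("MASAC", "AP", "ST", "41MAX", "ConSeg"):
        for style in ("rectangular", "irregular"):
            for i in range(n_cases):
                row = {"case": f"c{i}", "method": method, "mask_style": style}
                for f in features:
                    row[f] = base[f][i] + rng.normal(0, 0.05)
                rows.append(row)
    for i in range(n_cases):
        row = {"case": f"c{i}", "method": "GT", "mask_style": "GT"}
        for f in features:
            row[f] = base[f][i] + rng.normal(0, 0.05)
        rows.append(row)
    return pd.DataFrame(rows)


class TestRunDesign:
    def test_identical_raters_give_unit_icc(self):
        rng = np.random.default_rng(1)
        table = _feature_table(rng)
        # make irregular a copy of rectangular for one method
        rect = table[(table.method == "ST") & (table.mask_style == "rectangular")].copy()
        rect["mask_style"] = "irregular"
        table = pd.concat(
            [table[~((table.method == "ST") & (table.mask_style == "irregular"))], rect]
        )
        out = run_design(table, DesignSpec("between_masks", method="ST"))
        assert np.allclose(out["icc"], 1.0)

    def test_between_masks_dimensions(self):
        table = _feature_table(np.random.default_rng(2))
        out = run_design(table, DesignSpec("between_masks", method="ConSeg"))
        assert out.attrs["n_subjects"] == 13
        assert out.attrs["n_raters"] == 2
        assert len(out) == 3

    def test_among_methods_uses_four_raters(self):
        table = _feature_table(np.random.default_rng(3))
        out = run_design(table, DesignSpec("among_methods", mask_style="irregular"))
        assert out.attrs["n_raters"] == 4

    def test_vs_gt_uses_gt_rows(self):
        table = _feature_table(np.random.default_rng(4))
        out = run_design(
            table, DesignSpec("vs_ground_truth", method="ConSeg", mask_style="irregular")
        )
        assert out.attrs["n_raters"] == 2
        assert (out["icc"] > 0.9).all()  # tiny noise on a common base

    def test_subject_permutation_invariance(self):
        rng = np.random.default_rng(5)
        table = _feature_table(rng)
        a = run_design(table, DesignSpec("between_masks", method="AP"))
        shuffled = table.sample(frac=1.0, random_state=11).reset_index(drop=True)
        b = run_design(shuffled, DesignSpec("between_masks", method="AP"))
        for f in a.index:
            assert a.loc[f, "icc"] == pytest.approx(b.loc[f, "icc"], abs=1e-12)

    def test_missing_rater_named_in_error(self):
        table = _feature_table(np.random.default_rng(6))
        table = table[table.method != "AP"]
        with pytest.raises(KeyError, match="AP"):
            run_design(table, DesignSpec("among_methods", mask_style="irregular"))

    def test_invalid_feature_excluded_and_counted(self):
        table = _feature_table(np.random.default_rng(7))
        table.loc[table.index[0], "f1"] = np.nan
        method = table.loc[table.index[0], "method"]
        style = table.loc[table.index[0], "mask_style"]
        out = run_design(table, DesignSpec("between_masks", method=method))
        assert out.attrs["n_excluded_invalid"] == 1
        assert "f1" not in out.index


class TestSummarize:
    def test_all_unit_icc(self):
        tab = pd.DataFrame(
            {
                "icc": [1.0] * 5,
                "category": ["excellent"] * 5,
                "negative": [False] * 5,
                "valid": [True] * 5,
            },
            index=[f"f{i}" for i in range(5)],
        )
        s = summarize(tab)
        assert s.counts == {"excellent": 5, "good": 0, "moderate": 0, "poor": 0}
        assert s.median_icc == 1.0

    def test_counts_conserve_and_negatives_reported(self):
        rng = np.random.default_rng(8)
        iccs = rng.uniform(-0.2, 1.0, size=40)
        tab = pd.DataFrame(
            {
                "icc": iccs,
                "category": [categorize_icc(v) for v in iccs],
                "negative": iccs < 0,
                "valid": [True] * 40,
            },
            index=[f"f{i}" for i in range(40)],
        )
        s = summarize(tab)
        assert sum(s.counts.values()) + s.n_negative_excluded == 40
        assert s.n_negative_excluded == int((iccs < 0).sum())

    def test_stable_set_intersection_and_percent(self):
        idx = [f"f{i}" for i in range(10)]

        def tab(vals):
            return pd.DataFrame(
                {
                    "icc": vals,
                    "category": [categorize_icc(v) for v in vals],
                    "negative": [v < 0 for v in vals],
                    "valid": [True] * len(vals),
                },
                index=idx,
            )

        t1 = tab([0.9] * 6 + [0.2] * 4)
        t2 = tab([0.8] * 8 + [0.2] * 2)
        stable = stable_features({"a": t1, "b": t2})
        assert stable == [f"f{i}" for i in range(6)]
        assert 100 * len(stable) / 10 == pytest.approx(60.0)

    def test_noise_degrades_median_icc(self):
        rng = np.random.default_rng(9)
        n = 20
        base = rng.uniform(0, 10, size=n)
        medians = []
        for sigma in (0.05, 0.5, 2.0):
            iccs = []
            for _ in range(50):
                m = np.column_stack([base, base + rng.normal(0, sigma, size=n)])
                iccs.append(icc_a1(m).icc)
            medians.append(np.median(iccs))
        assert medians[0] > medians[1] > medians[2]
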