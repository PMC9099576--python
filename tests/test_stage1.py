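"""Stage 1: class assignment, editing, relationship matrix, MME solutions,
genetic parameters, BLUE extraction and PCA."""

import warnings

import numpy as np
import pandas as pd
import pytest

from spectragp import stage1
from spectragp.errors import (AlignmentError, DegenerateStatisticError,
                              PedigreeCycleError, RankError)
from spectragp.pedigree import AMatrix, build_a_matrix
from tests.conftest import toy_records


class TestAssignClasses:
    @pytest.mark.parametrize("date,season", [
        ("2015-02-01", 1), ("2015-05-10", 2), ("2015-08-31", 3), ("2015-12-25", 4),
    ])
    def test_calendar_quarter_seasons(self, date, season):
        rec = pd.DataFrame({"cow_id": ["c"], "sire_id": ["s"], "herd_id": ["h"],
                            "test_date": [date], "lactation_number": [1], "dim": [50]})
        out = stage1.assign_classes(rec)
        assert out.loc[0, "season"] == season
        assert out.loc[0, "hys_id"] == f"h_2015_{season}"

    def test_open_fourth_lactation_class(self):
        rec = pd.DataFrame({"cow_id": list("ab"), "sire_id": ["s"] * 2,
                            "herd_id": ["h"] * 2, "test_date": ["2015-05-10"] * 2,
                            "lactation_number": [4, 6], "dim": [100, 100]})
        out = stage1.assign_classes(rec)
        assert out.loc[0, "nsl_id"] == out.loc[1, "nsl_id"]

    def test_late_lactation_open_stage_class(self):
        rec = pd.DataFrame({"cow_id": ["a"], "sire_id": ["s"], "herd_id": ["h"],
                            "test_date": ["2015-05-10"], "lactation_number": [1],
                            "dim": [520]})
        assert stage1.assign_classes(rec).loc[0, "stage"] == 13

    def test_nsl_range_and_formula(self):
        rec = pd.DataFrame({"cow_id": ["a"], "sire_id": ["s"], "herd_id": ["h"],
                            "test_date": ["2015-05-10"], "lactation_number": [2],
                            "dim": [31]})
        # lactation class 2, stage ceil(31/30.4) = 2 -> 13*1 + 2 = 15
        assert stage1.assign_classes(rec).loc[0, "nsl_id"] == 15

    def test_missing_date_flagged_invalid(self):
        rec = pd.DataFrame({"cow_id": ["a"], "sire_id": ["s"], "herd_id": ["h"],
                            "test_date": [None], "lactation_number": [1], "dim": [10]})
        assert not stage1.assign_classes(rec).loc[0, "class_valid"]


class TestEditing:
    def test_dim_cutoff(self):
        rows = [(f"c{i}", "s", "h", "h_1", 1, d, 0.0) for i, d in
                enumerate([100, 540, 541])]
        df = toy_records(rows)
        out = stage1.apply_editing(df, stage1.EditThresholds(540, 0, 0, np.inf))
        assert set(out["dim"]) == {100, 540}

    def test_identity_thresholds(self, edited_records):
        th = stage1.EditThresholds(max_dim=10**9, min_cow_records=0,
                                   min_hys_size=0, spectral_sd=np.inf)
        out = stage1.apply_editing(edited_records, th)
        assert len(out) == len(edited_records)

    def test_cascade_fixed_point_on_toy(self):
        """Removing a small HYS drops a cow below the record minimum; the cow's
        other records must then go too, and re-application changes nothing."""
        rows = []
        # cow c1: 3 records in big HYS h_1, 1 record in tiny HYS h_2
        rows += [("c1", "s", "h", "h_1", 1, 50, 1.0)] * 3
        rows += [("c1", "s", "h", "h_2", 1, 80, 1.0)]
        # filler cows keeping h_1 large
        for i in range(4):
            rows += [(f"f{i}", "s", "h", "h_1", 1, 50, 0.0)] * 4
        df = toy_records(rows).reset_index(drop=True)
        th = stage1.EditThresholds(540, 4, 3, np.inf)

        # independent brute-force fixed point
        ref = df.copy()
        while True:
            n = len(ref)
            ref = ref[ref.groupby("cow_id")["cow_id"].transform("size") >= 4]
            ref = ref[ref.groupby("hys_id")["hys_id"].transform("size") >= 3]
            if len(ref) == n:
                break

        out = stage1.apply_editing(df, th)
        assert sorted(out.index) == sorted(ref.index)
        assert "c1" not in set(out["cow_id"])  # cascade removed the cow entirely
        again = stage1.apply_editing(out, th)
        pd.testing.assert_frame_equal(out.reset_index(drop=True),
                                      again.reset_index(drop=True))

    def test_spectral_outlier_removed_and_idempotent(self):
        rng = np.random.default_rng(0)
        df = toy_records([(f"c{i}", "s", "h", "h_1", 1, 50, 0.0) for i in range(60)])
        df["wvn_0001"] = rng.standard_normal(60)
        df.loc[0, "wvn_0001"] = 30.0
        out = stage1.apply_editing(df, stage1.EditThresholds(540, 0, 0, 5.0))
        assert 0 not in out.index
        pd.testing.assert_frame_equal(stage1.apply_editing(out,
                                      stage1.EditThresholds(540, 0, 0, 5.0)), out)

    def test_editing_idempotent_on_real_records(self, small_dataset):
        th = stage1.EditThresholds(min_cow_records=8, min_hys_size=8)
        rec = stage1.assign_classes(small_dataset.records)
        once = stage1.apply_editing(rec, th)
        twice = stage1.apply_editing(once, th)
        pd.testing.assert_frame_equal(once, twice)


class TestAMatrix:
    def test_single_founder(self):
        ped = pd.DataFrame({"id": ["x"], "sire": ["0"], "dam": ["0"]})
        a = build_a_matrix(ped)
        assert a.values.tolist() == [[1.0]]

    def test_sire_daughter_pair(self):
        ped = pd.DataFrame({"id": ["s", "d"], "sire": ["0", "s"], "dam": ["0", "0"]})
        a = build_a_matrix(ped).to_frame()
        assert a.loc["s", "d"] == 0.5
        assert a.loc["s", "s"] == 1.0 and a.loc["d", "d"] == 1.0

    def test_full_sib_mating_against_recursive_oracle(self):
        # founders A, B; full sibs C, D; E = C x D is inbred (diagonal 1.25)
        ped = pd.DataFrame({
            "id": ["A", "B", "C", "D", "E", "F"],
            "sire": ["0", "0", "A", "A", "C", "C"],
            "dam": ["0", "0", "B", "B", "D", "0"],
        })

        parents = {r.id: (r.sire if r.sire != "0" else None,
                          r.dam if r.dam != "0" else None)
                   for r in ped.itertuples()}

        def a_oracle(i, j, memo={}):
            if i is None or j is None:
                return 0.0
            key = (min(i, j), max(i, j))
            if key in memo:
                return memo[key]
            order = list(parents)
            if i == j:
                s, d = parents[i]
                val = 1.0 + 0.5 * a_oracle(s, d)
            else:
                late = i if order.index(i) > order.index(j) else j
                other = j if late == i else i
                s, d = parents[late]
                val = 0.5 * (a_oracle(other, s) + a_oracle(other, d))
            memo[key] = val
            return val

        a = build_a_matrix(ped).to_frame()
        for i in parents:
            for j in parents:
                assert a.loc[i, j] == pytest.approx(a_oracle(i, j), abs=1e-12)
        assert a.loc["E", "E"] == pytest.approx(1.25)

    def test_unsorted_pedigree_handled(self):
        ped = pd.DataFrame({"id": ["d", "s"], "sire": ["s", "0"], "dam": ["0", "0"]})
        a = build_a_matrix(ped).to_frame()
        assert a.loc["s", "d"] == 0.5

    def test_cycle_raises(self):
        ped = pd.DataFrame({"id": ["a", "b"], "sire": ["b", "a"], "dam": ["0", "0"]})
        with pytest.raises(PedigreeCycleError):
            build_a_matrix(ped)


class TestGeneticParameters:
    @pytest.mark.parametrize("vc,expected", [
        ((2, 2, 6), (0.20, 0.40)),
        ((0, 0, 1), (0.0, 0.0)),
        ((1, 0, 0), (1.0, 1.0)),
        ((0.11, 0.23, 0.66), (0.11, 0.34)),
    ])
    def test_h2_r2(self, vc, expected):
        h2, r2 = stage1.genetic_parameters(stage1.VarianceComponents(*vc))
        assert h2 == pytest.approx(expected[0])
        assert r2 == pytest.approx(expected[1])
        assert r2 >= h2

    def test_all_zero_undefined(self):
        with pytest.raises(DegenerateStatisticError):
            stage1.genetic_parameters(stage1.VarianceComponents(0, 0, 0))


def _gls_oracle(records, a, vc):
    """Dense GLS / BLUP oracle for the repeatability model, with the same
    identifiability convention as the solver (NSL reference level, sum-to-zero
    recentring)."""
    nsl, nsl_levels = pd.factorize(records["nsl_id"], sort=True)
    hys, hys_levels = pd.factorize(records["hys_id"], sort=True)
    cow, cow_levels = pd.factorize(records["cow_id"], sort=True)
    ids = list(a.ids)
    anim = records["cow_id"].map({i: k for k, i in enumerate(ids)}).to_numpy()
    n = len(records)
    x_nsl = np.zeros((n, len(nsl_levels) - 1))
    for r, c in enumerate(nsl):
        if c > 0:
            x_nsl[r, c - 1] = 1
    x_hys = np.eye(len(hys_levels))[hys]
    x = np.hstack([x_nsl, x_hys])
    z_a = np.zeros((n, len(ids)))
    z_a[np.arange(n), anim] = 1
    z_p = np.eye(len(cow_levels))[cow]
    v = (vc.sigma_a2 * z_a @ a.values @ z_a.T + vc.sigma_p2 * z_p @ z_p.T
         + vc.sigma_e2 * np.eye(n))
    vinv = np.linalg.inv(v)
    y = records["my"].to_numpy(dtype=float)
    b = np.linalg.solve(x.T @ vinv @ x, x.T @ vinv @ y)
    resid = y - x @ b
    a_hat = vc.sigma_a2 * a.values @ z_a.T @ vinv @ resid
    p_hat = vc.sigma_p2 * z_p.T @ vinv @ resid
    nsl_sol = np.concatenate([[0.0], b[: len(nsl_levels) - 1]])
    hys_sol = b[len(nsl_levels) - 1:]
    shift = nsl_sol.mean()
    return (pd.Series(nsl_sol - shift, index=nsl_levels),
            pd.Series(hys_sol + shift, index=hys_levels),
            pd.Series(a_hat, index=ids), pd.Series(p_hat, index=cow_levels))


@pytest.fixture()
def mme_toy():
    """12 records, 2 HYS, 2 NSL, 3 cows sired by one genotyped bull."""
    ped = pd.DataFrame({"id": ["s1", "c1", "c2", "c3"],
                        "sire": ["0", "s1", "s1", "0"], "dam": ["0"] * 4})
    a = build_a_matrix(ped)
    rng = np.random.default_rng(4)
    rows = []
    for i, cowid in enumerate(["c1", "c2", "c3"] * 4):
        rows.append((cowid, "s1", "h", f"h_{i % 2 + 1}", (i // 2) % 2 + 1, 50 + i, 0.0))
    df = toy_records(rows)
    df["my"] = rng.standard_normal(len(df)) + np.linspace(0, 2, len(df))
    return df, a


class TestMmeSolver:
    def test_matches_dense_gls_oracle(self, mme_toy):
        df, a = mme_toy
        vc = stage1.VarianceComponents(1.5, 0.8, 2.0)
        fit = stage1.solve_mme_fixed_vc(df, "my", a, vc)
        nsl_o, hys_o, a_o, p_o = _gls_oracle(df, a, vc)
        assert np.abs(fit.hys["blue"] - hys_o).max() < 1e-8
        assert np.abs(fit.nsl["blue"] - nsl_o).max() < 1e-8
        assert np.abs(fit.blup_a - a_o).max() < 1e-8
        assert np.abs(fit.blup_p - p_o).max() < 1e-8

    def test_gls_oracle_on_random_toys(self):
        rng = np.random.default_rng(8)
        for t in range(3):
            ped = pd.DataFrame({"id": ["s1", "s2", "c1", "c2", "c3", "c4"],
                                "sire": ["0", "0", "s1", "s1", "s2", "s2"],
                                "dam": ["0"] * 6})
            a = build_a_matrix(ped)
            rows = []
            for i in range(20 + t):
                cow = f"c{rng.integers(1, 5)}"
                rows.append((cow, "s", "h", f"h_{rng.integers(1, 4)}",
                             int(rng.integers(1, 4)), 50, float(rng.standard_normal())))
            df = toy_records(rows)
            df["my"] = rng.standard_normal(len(df))
            vc = stage1.VarianceComponents(*rng.uniform(0.5, 3, 3))
            fit = stage1.solve_mme_fixed_vc(df, "my", a, vc)
            _, hys_o, a_o, _ = _gls_oracle(df, a, vc)
            assert np.abs(fit.hys["blue"] - hys_o).max() < 1e-6
            assert np.abs(fit.blup_a - a_o).max() < 1e-6

    def test_ols_limit_no_random_effects(self, mme_toy):
        df, a = mme_toy
        vc = stage1.VarianceComponents(0.0, 0.0, 1.0)
        fit = stage1.solve_mme_fixed_vc(df, "my", a, vc)
        # OLS oracle with the same constraint and recentring
        nsl_o, hys_o, _, _ = _gls_oracle(df, a, vc)
        assert np.abs(fit.hys["blue"] - hys_o).max() < 1e-8
        assert np.all(fit.blup_a == 0) and np.all(fit.blup_p == 0)

    def test_translation_invariance_of_hys_contrasts(self, mme_toy):
        df, a = mme_toy
        vc = stage1.VarianceComponents(1.0, 1.0, 2.0)
        fit0 = stage1.solve_mme_fixed_vc(df, "my", a, vc)
        df2 = df.copy()
        df2["my"] = df2["my"] + 7.0
        fit1 = stage1.solve_mme_fixed_vc(df2, "my", a, vc)
        d0 = np.diff(fit0.hys["blue"].to_numpy())
        d1 = np.diff(fit1.hys["blue"].to_numpy())
        assert np.abs(d0 - d1).max() < 1e-8

    def test_aliased_fixed_effects_raise_rank_error(self):
        # NSL and HYS classes coincide record-by-record -> aliased columns
        ped = pd.DataFrame({"id": ["c1", "c2"], "sire": ["0", "0"], "dam": ["0", "0"]})
        a = build_a_matrix(ped)
        rows = [("c1", "s", "h", "h_1", 1, 50, 1.0)] * 3 + \
               [("c2", "s", "h", "h_2", 2, 50, 2.0)] * 3
        df = toy_records(rows)
        df["my"] = [1.0, 2, 3, 4, 5, 6]
        with pytest.raises(RankError):
            stage1.solve_mme_fixed_vc(df, "my", a,
                                      stage1.VarianceComponents(0, 0, 1.0))


class TestHysBlueTable:
    def _fits(self, hys_ids, values):
        fits = {}
        for name, vals in values.items():
            hys = pd.DataFrame({"blue": vals, "se": np.ones(len(hys_ids))},
                               index=pd.Index(hys_ids, name="hys_id"))
            fits[name] = stage1.ModelFit(name, hys, pd.DataFrame(),
                                         pd.Series(dtype=float), pd.Series(dtype=float),
                                         stage1.VarianceComponents(1, 1, 1))
        return fits

    def test_standardized_columns(self):
        rng = np.random.default_rng(0)
        ids = [f"h_{i}" for i in range(30)]
        table = stage1.extract_hys_blues(self._fits(ids, {
            "my": rng.standard_normal(30) * 3 + 1,
            "scs": rng.standard_normal(30)}))
        assert np.abs(table.std.mean()).max() < 1e-10
        assert np.abs(table.std.var(ddof=0) - 1).max() < 1e-8

    def test_constant_column_dropped_with_warning(self):
        ids = [f"h_{i}" for i in range(10)]
        with pytest.warns(UserWarning, match="constant BLUE"):
            table = stage1.extract_hys_blues(self._fits(ids, {
                "my": np.arange(10.0), "flat": np.ones(10)}))
        assert list(table.std.columns) == ["my"]

    def test_misaligned_hys_sets_raise(self):
        f1 = self._fits([f"h_{i}" for i in range(5)], {"my": np.arange(5.0)})
        f2 = self._fits([f"h_{i}" for i in range(4)], {"scs": np.arange(4.0)})
        with pytest.raises(AlignmentError):
            stage1.extract_hys_blues({**f1, **f2})

    def test_recovery_of_true_hys_effects(self, small_dataset, my_fit):
        """Standardized HYS BLUEs track the generating HYS effects closely
        at ~30 records per class."""
        _, fit = my_fit
        true = small_dataset.truth.hys_effects["my"]
        est = fit.hys["blue"]
        common = est.index.intersection(true.index)
        r = np.corrcoef(est.loc[common], true.loc[common])[0, 1]
        assert r > 0.9


class TestPca:
    def _table(self, x, cols):
        df = pd.DataFrame(x, columns=cols,
                          index=[f"h_{i}" for i in range(len(x))])
        std = (df - df.mean()) / df.std(ddof=0)
        return stage1.HysBlueTable(df, df * np.nan, std)

    def test_duplicated_column_rank_one(self):
        x = np.linspace(-1, 1, 9)
        table = self._table(np.column_stack([x, x]), ["wvn_0001", "wvn_0002"])
        scores, cum = stage1.pca_hys_blues(table, 1)
        assert cum[-1] == pytest.approx(1.0, abs=1e-10)

    def test_cumulative_fraction_reaches_one_at_full_rank(self):
        rng = np.random.default_rng(2)
        table = self._table(rng.standard_normal((12, 3)),
                            ["wvn_0001", "wvn_0002", "wvn_0003"])
        _, cum = stage1.pca_hys_blues(table, 3)
        assert cum[-1] == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(cum) >= -1e-12)

    def test_eigenvalues_match_covariance_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((5, 3))
        table = self._table(x, ["wvn_0001", "wvn_0002", "wvn_0003"])
        scores, cum = stage1.pca_hys_blues(table, 3)
        xs = table.std.to_numpy()
        evals = np.sort(np.linalg.eigvalsh(np.cov(xs.T, ddof=1)))[::-1]
        assert np.allclose(scores.to_numpy().var(axis=0, ddof=1), evals, atol=1e-10)
        assert np.allclose(cum, np.cumsum(evals) / evals.sum(), atol=1e-10)

    def test_k_above_rank_rejected(self):
        x = np.linspace(-1, 1, 7)
        table = self._table(np.column_stack([x, 2 * x, -x]),
                            ["wvn_0001", "wvn_0002", "wvn_0003"])
        with pytest.raises(ValueError):
            stage1.pca_hys_blues(table, 2)
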