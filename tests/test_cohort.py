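import itertools
import math

import numpy as np
import pandas as pd
import pytest

from voitex.cohort import (
    build_feature_table,
    compare_groups,
    feature_columns,
    mann_whitney,
    reduce_between_distances,
    reduce_between_parameters,
    reduce_redundancy,
    spearman_rho,
)
from voitex.haralick import PARAMETER_NAMES
from voitex.io import VolumeWithMask
from voitex.synthetic import CohortSpec, make_cohort


def exact_mann_whitney_p(x, y):
    """Oracle: full enumeration of U over all group-label assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pd.Series(pooled).rank().values

    def u_of(idx):
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    mean_u = n1 * (len(y)) / 2
    us = [u_of(c) for c in itertools.combinations(range(len(pooled)), n1)]
    extreme = sum(abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9 for u in us)
    return extreme / len(us)


class TestSpearman:
    def test_identity_and_reversal(self):
        assert spearman_rho([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_textbook_rank_formula(self):
        # d^2 = (1,1,1,1): rho = 1 - 6*4/(4*15) = 0.6
        assert spearman_rho([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_constant_vector_is_missing(self):
        assert math.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(base)
        assert spearman_rho(x, y**3) == pytest.approx(base)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [3, 4])


class TestMannWhitney:
    def test_small_exact_example(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.u == 0
        assert res.p_value == pytest.approx(1 / 3)
        assert res.method == "exact"

    def test_exchangeable_groups_p_one(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.method == "asymptotic"  # ties force the corrected path
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_8_vs_10(self):
        x = np.arange(1, 9)
        y = np.arange(9, 19)
        res = mann_whitney(x, y)
        assert res.u == 0
        assert res.p_value == pytest.approx(2 / math.comb(18, 8), rel=1e-9)

    @pytest.mark.parametrize("n1,n2", [(2, 2), (2, 4), (3, 3), (4, 5), (6, 6)])
    def test_matches_enumeration_oracle(self, rng, n1, n2):
        for _ in range(3):
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # distinct
            x, y = pooled[:n1], pooled[n1:]
            res = mann_whitney(x, y)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(exact_mann_whitney_p(x, y))

    def test_errors(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2, 3])
        with pytest.raises(ValueError):
            mann_whitney([1], [2])


def _table_from_columns(columns: dict, n=18) -> pd.DataFrame:
    df = pd.DataFrame(columns)
    df.index = [f"S{i:02d}" for i in range(len(df))]
    df.index.name = "subject_id"
    return df


def _full_table(rng, n=18):
    cols = {c: rng.normal(size=n) for c in feature_columns()}
    df = _table_from_columns(cols, n)
    df.insert(0, "group", ["AB"] * 8 + ["OKC"] * (n - 8))
    return df


class TestReduceBetweenDistances:
    def test_monotone_distance_columns_collapse_to_q3(self, rng):
        base = {p: rng.normal(size=18) for p in PARAMETER_NAMES}
        cols = {}
        for p in PARAMETER_NAMES:
            for k, lab in enumerate(["q1", "q2", "q3", "q4", "q5"]):
                cols[f"{p}@{lab}"] = np.exp(base[p]) * (k + 1)  # monotone
        step = reduce_between_distances(_table_from_columns(cols))
        assert step.reference_distance == "q3"
        assert step.failed == []
        for mat in step.between_distance_rho.values():
            off = mat.values[~np.eye(5, dtype=bool)]
            np.testing.assert_allclose(off, 1.0)

    def test_independent_column_flagged(self, rng):
        base = {p: rng.normal(size=18) for p in PARAMETER_NAMES}
        cols = {}
        for p in PARAMETER_NAMES:
            for lab in ["q1", "q2", "q3", "q4", "q5"]:
                cols[f"{p}@{lab}"] = base[p]
        cols["contrast@q5"] = rng.normal(size=18)  # break one parameter
        step = reduce_between_distances(_table_from_columns(cols))
        assert step.failed == ["contrast"]
        assert step.reference_distance == "q3"

    def test_too_few_subjects_rejected(self, rng):
        cols = {f"{p}@q{k}": rng.normal(size=2) for p in PARAMETER_NAMES for k in (1, 2)}
        with pytest.raises(ValueError):
            reduce_between_distances(_table_from_columns(cols, n=2))


class TestReduceBetweenParameters:
    def test_duplicate_column_excluded_against_original(self, rng):
        cols = {f"{p}@q3": rng.normal(size=18) for p in PARAMETER_NAMES}
        cols["sum_entropy@q3"] = cols["entropy@q3"].copy()
        report = reduce_between_parameters(_table_from_columns(cols))
        assert report.excluded_names == ["sum_entropy"]
        exc = report.excluded[0]
        assert exc.partner == "entropy"
        assert exc.rho == pytest.approx(1.0)

    def test_independent_columns_nothing_excluded(self):
        rng = np.random.default_rng(7)
        cols = {f"{p}@q3": rng.normal(size=18) for p in PARAMETER_NAMES}
        report = reduce_between_parameters(_table_from_columns(cols))
        assert report.excluded == []
        assert len(report.retained) == 11

    def test_idempotent_on_retained_set(self, rng):
        cols = {f"{p}@q3": rng.normal(size=18) for p in PARAMETER_NAMES}
        cols["sum_variance@q3"] = cols["variance@q3"] * 2 + 0.01 * rng.normal(size=18)
        first = reduce_between_parameters(_table_from_columns(cols))
        retained_cols = {f"{p}@q3": cols[f"{p}@q3"] for p in first.retained}
        second = reduce_between_parameters(_table_from_columns(retained_cols))
        assert second.excluded == []

    def test_partition_invariant(self, rng):
        cols = {f"{p}@q3": rng.normal(size=18) for p in PARAMETER_NAMES}
        cols["entropy_of_difference@q3"] = -cols["contrast@q3"]
        report = reduce_between_parameters(_table_from_columns(cols))
        assert sorted(report.retained + report.excluded_names) == sorted(
            PARAMETER_NAMES
        )
        for exc in report.excluded:
            assert abs(exc.rho) >= report.threshold
            assert exc.partner in report.retained + report.excluded_names


class TestPipelineStages:
    def test_feature_table_shape_on_default_cohort(self):
        cohort, _ = make_cohort(CohortSpec(master_seed=3))
        ft = build_feature_table(cohort)
        assert ft.shape == (18, 56)  # group + 55 variables
        assert list(ft.columns[1:]) == feature_columns()
        assert (ft["group"] == "AB").sum() == 8
        assert not ft.drop(columns="group").isna().any().any()

    def test_single_subject_refused_by_comparison(self, rng):
        ft = _full_table(rng).iloc[:1]
        red = reduce_redundancy(_full_table(rng).drop(columns="group"))
        with pytest.raises(ValueError):
            compare_groups(ft, red)

    def test_single_voxel_voi_gives_missing_row(self, rng, caplog):
        mask = np.zeros((8, 8, 4), dtype=bool)
        mask[4, 4, 2] = True
        vwm = VolumeWithMask(
            intensities=rng.normal(size=(8, 8, 4)),
            spacing=(1, 1, 1),
            mask=mask,
            subject_id="tiny",
            group_label="AB",
        )
        import logging

        with caplog.at_level(logging.WARNING):
            ft = build_feature_table([vwm])
        assert ft.drop(columns="group").isna().all().all()
        assert "degenerate" in caplog.text

    def test_compare_groups_rows_and_flags(self, rng):
        ft = _full_table(rng)
        # separate one parameter strongly between groups
        ft.loc[ft["group"] == "AB", "entropy@q3"] += 10
        red = reduce_redundancy(ft.drop(columns="group"))
        comp = compare_groups(ft, red)
        assert len(comp.table) == 2 * len(red.retained)
        ent = comp.table[comp.table["parameter"] == "entropy"]
        assert (ent["significant"]).all()
        assert set(ent["group"]) == {"AB", "OKC"}
        assert comp.table["method"].eq("exact").all()

    def test_markdown_report_contains_values(self, rng):
        ft = _full_table(rng)
        red = reduce_redundancy(ft.drop(columns="group"))
        comp = compare_groups(ft, red)
        md = comp.to_markdown()
        assert md.startswith("| Parameter | Group | N |")
        assert "| AB | 8 |" in md and "| OKC | 10 |" in md

    def test_label_permutation_null_rate(self, rng):
        """Permuting group labels should reject at roughly the alpha level."""
        cohort, _ = make_cohort(CohortSpec(master_seed=11))
        ft = build_feature_table(cohort)
        col = "entropy@q3"
        flags = []
        values = ft[col].values
        for _ in range(300):
            perm = rng.permutation(18)
            x, y = values[perm[:8]], values[perm[8:]]
            flags.append(mann_whitney(x, y).p_value <= 0.05)
        rate = np.mean(flags)
        assert 0.01 <= rate <= 0.10  # binomial band around 0.05, n=300
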