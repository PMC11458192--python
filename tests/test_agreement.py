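"""Contingency tables, Cohen's kappa (vs first-principles oracle), ICC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazesharp.agreement import (
    ContingencyTable,
    build_contingency,
    cohen_kappa,
    dichotomize,
    icc,
    load_table2,
)
from gazesharp.scoring import CLASS_BINS


def kappa_oracle(counts):
    """First-principles kappa: enumerate agreement and chance agreement."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    p_o = sum(counts[i, i] for i in range(len(counts))) / n
    p_e = sum(counts[i, :].sum() * counts[:, i].sum() for i in range(len(counts))) / n**2
    return (p_o - p_e) / (1 - p_e)


class TestBuildContingency:
    def test_counts_pairs(self):
        t = build_contingency([("0", "0"), ("0", "0"), ("1", "1")])
        assert t.counts[0, 0] == 2 and t.counts[1, 1] == 1
        assert t.n == 3

    def test_integer_classes_accepted(self):
        t = build_contingency([(0, 0), (3, 2)])
        assert t.counts[3, 2] == 1

    def test_empty_pairs_all_zero(self):
        t = build_contingency([])
        assert t.n == 0
        with pytest.raises(ValueError):
            cohen_kappa(t)

    def test_unknown_bin_rejected(self):
        with pytest.raises(ValueError, match="unknown bin"):
            build_contingency([("7", "0")])


class TestCohenKappa:
    def test_diagonal_table_is_perfect_agreement(self):
        t = ContingencyTable(bins=("0", "1", "2"), counts=np.diag([5, 3, 2]))
        r = cohen_kappa(t)
        assert r.kappa == pytest.approx(1.0)
        assert r.ci_low <= r.kappa <= r.ci_high

    def test_study_erosion_table(self):
        r = cohen_kappa(load_table2("erosion"))
        assert r.kappa == pytest.approx(0.8278, abs=5e-4)
        assert r.p_o == pytest.approx(384 / 414)
        assert r.p_e == pytest.approx(99272 / 171396)

    def test_study_jsn_table(self):
        r = cohen_kappa(load_table2("jsn"))
        assert r.kappa == pytest.approx(0.6821, abs=5e-4)
        assert r.p_o == pytest.approx(330 / 396)
        assert r.p_e == pytest.approx(74592 / 156816)

    def test_degenerate_single_cell_rejected(self):
        t = ContingencyTable(bins=("0", "1"), counts=np.array([[9, 0], [0, 0]]))
        with pytest.raises(ValueError, match="degenerate"):
            cohen_kappa(t)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 8, size=(4, 4))
        counts[0, 0] += 3  # avoid degeneracy
        perm = rng.permutation(4)
        k1 = cohen_kappa(ContingencyTable(bins=("a", "b", "c", "d"), counts=counts)).kappa
        k2 = cohen_kappa(
            ContingencyTable(bins=("a", "b", "c", "d"), counts=counts[np.ix_(perm, perm)])
        ).kappa
        assert k1 == pytest.approx(k2)

    @settings(deadline=None, max_examples=200)
    @given(
        st.integers(2, 4).flatmap(
            lambda k: st.lists(
                st.tuples(st.integers(0, k - 1), st.integers(0, k - 1)),
                min_size=2, max_size=20,
            ).map(lambda pairs: (k, pairs))
        )
    )
    def test_matches_first_principles_on_small_tables(self, k_pairs):
        k, pairs = k_pairs
        bins = tuple(str(i) for i in range(k))
        t = build_contingency(pairs, bins=bins)
        p = t.counts / t.n
        if float(p.sum(0) @ p.sum(1)) >= 1.0 - 1e-12:
            return  # degenerate, rejected elsewhere
        assert cohen_kappa(t).kappa == pytest.approx(kappa_oracle(t.counts), abs=1e-12)

    def test_kappa_bounds_and_ci_ordering(self):
        t = load_table2("jsn")
        r = cohen_kappa(t)
        assert -1.0 <= r.kappa <= 1.0
        assert r.ci_low <= r.kappa <= r.ci_high
        assert r.kappa == pytest.approx((r.p_o - r.p_e) / (1 - r.p_e))


class TestDichotomize:
    def test_erosion_collapses_to_published_2x2(self):
        d = dichotomize(load_table2("erosion"))
        assert d.counts.tolist() == [[307, 1], [3, 103]]
        assert cohen_kappa(d).kappa == pytest.approx(0.9745, abs=5e-4)

    def test_jsn_2x2_kappa(self):
        d = dichotomize(load_table2("jsn"))
        assert cohen_kappa(d).kappa == pytest.approx(0.9486, abs=5e-4)

    def test_diagonal_stays_diagonal(self):
        t = ContingencyTable(bins=CLASS_BINS, counts=np.diag([4, 3, 2, 1, 1, 1, 1]))
        d = dichotomize(t)
        assert d.counts.tolist() == [[4, 0], [0, 9]]

    def test_equals_kappa_on_binarized_pairs(self):
        rng = np.random.default_rng(3)
        pairs = [(str(min(a, 6)), str(min(b, 6)))
                 for a, b in rng.integers(0, 8, size=(60, 2)).tolist()]
        pairs = [(("≥6" if p == "6" else p), ("≥6" if q == "6" else q)) for p, q in pairs]
        t = build_contingency(pairs)
        direct = build_contingency(
            [("no" if p == "0" else "yes", "no" if q == "0" else "yes") for p, q in pairs],
            bins=("no", "yes"),
        )
        assert cohen_kappa(dichotomize(t)).kappa == pytest.approx(cohen_kappa(direct).kappa)

    def test_requires_zero_first_bin(self):
        t = ContingencyTable(bins=("1", "2"), counts=np.eye(2, dtype=int) * 3)
        with pytest.raises(ValueError):
            dichotomize(t)


def icc_oracle(arr):
    """Brute-force two-way ANOVA mean squares -> ICC(2,1)."""
    arr = np.asarray(arr, dtype=float)
    n, k = arr.shape
    grand = arr.mean()
    row_m = arr.mean(axis=1)
    col_m = arr.mean(axis=0)
    msr = k * ((row_m - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_m - grand) ** 2).sum() / (k - 1)
    resid = arr - row_m[:, None] - col_m[None, :] + grand
    mse = (resid**2).sum() / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_identical_replicates_give_one(self):
        col = np.array([0.0, 1, 2, 5, 3, 1])
        r = icc(np.column_stack([col, col]))
        assert r.icc == pytest.approx(1.0)

    def test_variance_components_recovery(self):
        # between-joint variance 4.0, within 0.25 -> ICC ~ 4/4.25 ~ 0.9412
        rng = np.random.default_rng(5)
        t = rng.normal(0.0, 2.0, 400)
        arr = np.column_stack([t + rng.normal(0, 0.5, 400), t + rng.normal(0, 0.5, 400)])
        r = icc(arr)
        assert r.icc == pytest.approx(4 / 4.25, abs=0.02)
        assert r.ci_low <= r.icc <= r.ci_high

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(8)
        arr = rng.normal(0, 1, size=(12, 2)) + rng.normal(0, 2, size=(12, 1))
        assert icc(arr).icc == pytest.approx(icc_oracle(arr), abs=1e-9)

    def test_uninformative_ratings_near_zero(self):
        rng = np.random.default_rng(2)
        arr = np.column_stack([np.zeros(30), rng.normal(0, 1, 30)])
        r = icc(arr)
        assert abs(r.icc) < 0.35
        assert r.icc == pytest.approx(icc_oracle(arr), abs=1e-9)

    def test_incomplete_rows_dropped_and_minimum_enforced(self):
        arr = np.array([[1.0, np.nan], [2.0, 2.0]])
        with pytest.raises(ValueError, match=">= 2 joints"):
            icc(arr)

    def test_one_column_rejected(self):
        with pytest.raises(ValueError):
            icc(np.zeros((5, 1)))


class TestFixtures:
    def test_jsn_body_mass_is_396(self):
        assert load_table2("jsn").n == 396

    def test_erosion_body_mass_is_414(self):
        # table body sums to 414 although 416 joints were analyzable
        assert load_table2("erosion").n == 414

    def test_csv_round_trip(self, tmp_path):
        t = load_table2("erosion")
        p = tmp_path / "t.csv"
        t.to_csv(p)
        back = ContingencyTable.from_csv(p)
        assert back.bins == t.bins
        assert (back.counts == t.counts).all()

    def test_unknown_lesion_rejected(self):
        with pytest.raises(ValueError):
            load_table2("synovitis")
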