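"""Correlation pruning, standardization and the Mann-Whitney U machinery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

import timask.stats as st
from timask.errors import ParameterError, ValidationError
from timask.io import PARAMETER_NAMES
from timask.masking import MaskingResult


def _matrix(columns: dict, standardized=False):
    n = len(next(iter(columns.values())))
    df = pd.DataFrame(columns, index=[f"m{i:02d}" for i in range(n)])
    return st.ParameterMatrix(df, standardized=standardized)


class TestPearson:
    def test_known_values(self):
        m = _matrix({"Imax": [1.0, 2.0, 3.0], "AreaDec": [1.0, 2.0, 4.0]})
        r = st.pearson_corr_matrix(m)
        assert r.loc["Imax", "Imax"] == pytest.approx(1.0)
        assert r.loc["Imax", "AreaDec"] == pytest.approx(0.9820, abs=5e-5)
        assert np.allclose(r.to_numpy(), r.to_numpy().T)

    def test_anticorrelated(self):
        m = _matrix({"Imax": [1.0, 2.0, 3.0], "Tstart": [3.0, 2.0, 1.0]})
        assert st.pearson_corr_matrix(m).loc["Imax", "Tstart"] == pytest.approx(-1.0)

    def test_constant_column_named(self):
        m = _matrix({"Imax": [1.0, 2.0, 3.0], "DurPl": [0.0, 0.0, 0.0]})
        with pytest.raises(ValidationError, match="DurPl"):
            st.pearson_corr_matrix(m)


class TestStandardize:
    def test_hand_computed(self):
        z = st.standardize(_matrix({"Imax": [1.0, 2.0, 3.0]}))
        assert np.allclose(z.data["Imax"], [-1.224745, 0.0, 1.224745], atol=5e-7)
        assert z.standardized

    def test_idempotent(self):
        z1 = st.standardize(_matrix({"Imax": [4.0, 9.0, 1.0, 7.0]}))
        z2 = st.standardize(z1)
        assert np.allclose(z1.data, z2.data, atol=1e-12)

    def test_scale_and_shift_invariant(self):
        base = _matrix({"Imax": [4.0, 9.0, 1.0, 7.0]})
        moved = _matrix({"Imax": [1000.0 * v + 37.0 for v in [4.0, 9.0, 1.0, 7.0]]})
        assert np.allclose(st.standardize(base).data, st.standardize(moved).data)

    def test_constant_column_rejected(self):
        with pytest.raises(ValidationError):
            st.standardize(_matrix({"Imax": [5.0, 5.0, 5.0]}))


def _mwu_enumeration_oracle(a, b):
    """Exact two-tailed p by enumerating all C(n+m, n) group assignments."""
    pooled = np.concatenate([a, b])
    n = len(a)
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}

    def u_of(idx_set):
        rank_sum = sum(ranks[pooled[i]] for i in idx_set)
        u1 = rank_sum - n * (n + 1) / 2
        return min(u1, n * len(b) - u1)

    observed = u_of(range(n))
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        total += 1
        if u_of(combo) <= observed:
            hits += 1
    return hits / total


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        res = st.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert (res.U, res.p, res.method) == (0.0, 0.1, "exact")

    def test_identical_tied_groups_p_one(self):
        res = st.mann_whitney_u([1, 2], [1, 2])
        assert res.p == 1.0

    def test_symmetric_in_groups(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 7), rng.normal(1, 1, 5)
        r1, r2 = st.mann_whitney_u(a, b), st.mann_whitney_u(b, a)
        assert r1.U == r2.U and r1.p == pytest.approx(r2.p)

    def test_small_group_rejected(self):
        with pytest.raises(ParameterError):
            st.mann_whitney_u([1.0], [2.0, 3.0])

    @settings(max_examples=60)
    @given(hst.integers(2, 6), hst.integers(2, 6), hst.randoms(use_true_random=False))
    def test_exact_p_matches_enumeration(self, n, m, rnd):
        """Exact path equals the brute-force null enumeration, tie-free n+m <= 12."""
        pooled = rnd.sample(range(1000), n + m)
        a, b = [float(v) for v in pooled[:n]], [float(v) for v in pooled[n:]]
        res = st.mann_whitney_u(a, b, method="exact")
        assert res.p == pytest.approx(_mwu_enumeration_oracle(a, b), abs=1e-12)

    def test_exact_and_asymptotic_agree_at_study_size(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b = rng.normal(0, 1, 10), rng.normal(0.8, 1, 10)
            pe = st.mann_whitney_u(a, b, method="exact").p
            pa = st.mann_whitney_u(a, b, method="asymptotic").p
            assert abs(pe - pa) < 0.02


def _fourteen_column_matrix(n=30, seed=0):
    """All 14 columns with the collinearity pattern of a real study:
    TsPl = TePl, Tend tracks DurDec, AreaTse tracks AreaDec, plateau zero."""
    rng = np.random.default_rng(seed)
    t_start = rng.uniform(5.5, 6.5, n)
    dur_inc = rng.uniform(4, 22, n)
    imax = rng.uniform(30, 90, n)
    dur_dec = rng.uniform(40, 260, n)
    area_dec = dur_dec * (imax - 1) / np.log(imax)
    cols = {
        "Tstart": t_start, "Tend": t_start + dur_inc + dur_dec, "Imax": imax,
        "TsPl": t_start + dur_inc, "TePl": t_start + dur_inc,
        "DurPl": np.zeros(n), "DurInc": dur_inc, "DurDec": dur_dec,
        "SIMInc": imax / dur_inc, "SIMDec": imax * np.log(imax) / dur_dec,
        "AreaTse": 0.5 * imax * dur_inc + area_dec,
        "AreaInc": 0.5 * imax * dur_inc, "AreaDec": area_dec,
        "AreaPl": np.zeros(n),
    }
    return _matrix(cols)


class TestPrune:
    def test_study_structure_keeps_eight(self):
        retained, report = st.prune_correlated(_fourteen_column_matrix())
        assert retained == ["Tstart", "Imax", "DurInc", "DurDec",
                           "SIMInc", "SIMDec", "AreaInc", "AreaDec"]
        reasons = {e.column: e for e in report}
        assert "plateau" in reasons["DurPl"].reason
        assert reasons["Tend"].kept == "DurDec" and abs(reasons["Tend"].r) >= 0.98
        assert reasons["AreaTse"].kept == "AreaDec"
        assert reasons["TsPl"].kept == "DurInc" and reasons["TePl"].kept == "DurInc"

    def test_unattainable_threshold_prunes_only_zero_plateau(self):
        retained, _ = st.prune_correlated(_fourteen_column_matrix(), r_threshold=1.01)
        assert retained == [c for c in PARAMETER_NAMES if c not in ("DurPl", "AreaPl")]

    def test_exact_multiple_grouped(self):
        m = _fourteen_column_matrix()
        m.data["AreaInc"] = 2.0 * m.data["SIMInc"]  # r = 1 by construction
        retained, report = st.prune_correlated(m, mode="auto")
        assert ("AreaInc" in retained) != ("SIMInc" in retained)
        dropped = {e.column for e in report}
        assert ("AreaInc" in dropped) or ("SIMInc" in dropped)

    def test_retained_set_has_no_high_correlation_pair(self, default_run):
        retained, _ = st.prune_correlated(default_run.matrix, r_threshold=0.98)
        r = st.pearson_corr_matrix(default_run.matrix.select(retained)).to_numpy()
        off = np.abs(r[~np.eye(len(retained), dtype=bool)])
        assert off.max() < 0.98

    def test_unknown_mode_rejected(self):
        with pytest.raises(ParameterError):
            st.prune_correlated(_fourteen_column_matrix(), mode="bogus")

    def test_missing_columns_rejected(self):
        with pytest.raises(ValidationError, match="missing"):
            st.prune_correlated(_matrix({"Imax": [1.0, 2.0, 3.0]}))


class TestCompareTopBottom:
    def _setup(self, top_offset):
        rng = np.random.default_rng(2)
        ids = [f"m{i:02d}" for i in range(20)]
        scores = np.r_[np.linspace(9, 8, 10), np.linspace(2, 1, 10)]
        masking = [MaskingResult(i, 10 - s, s, 10) for i, s in zip(ids, scores)]
        sep = np.r_[rng.uniform(5, 6, 10) + top_offset, rng.uniform(5, 6, 10)]
        flat = rng.uniform(0, 1, 20)
        df = pd.DataFrame({"AreaDec": sep, "Tstart": flat}, index=ids)
        return st.ParameterMatrix(df), masking

    def test_full_separation_hits_exact_tail(self):
        params, masking = self._setup(top_offset=10.0)
        comps = {c.parameter: c for c in st.compare_top_bottom(params, masking, k=10)}
        c = comps["AreaDec"]
        assert c.U == 0.0
        assert c.p_two_tailed == pytest.approx(2 / math.comb(20, 10))
        assert c.significant
        assert not comps["Tstart"].significant

    def test_identical_groups_not_significant(self):
        params, masking = self._setup(top_offset=0.0)
        same = params.data.copy()
        same["AreaDec"] = np.tile(np.arange(10.0), 2)
        comps = st.compare_top_bottom(st.ParameterMatrix(same), masking, k=10)
        assert not any(c.significant for c in comps)

    def test_mismatched_materials_rejected(self):
        params, masking = self._setup(10.0)
        with pytest.raises(ValidationError):
            st.compare_top_bottom(params, masking[:-1], k=9)
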