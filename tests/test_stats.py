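"""Signed-KS statistic, bootstrap null, reliability filter, Z assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st
from scipy import stats as sps

from phenoks import stats as pks
from conftest import brute_force_signed_ks

finite_floats = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)
samples = st.lists(finite_floats, min_size=1, max_size=20)


class TestSignedKS:
    @pytest.mark.parametrize("treated, control, expected", [
        ([1, 2, 3], [1, 2, 3], 0.0),          # identical samples
        ([4, 5, 6], [1, 2, 3], +1.0),         # complete upward shift
        ([1, 3], [2, 4], -0.5),               # interleaved, shifted down
    ])
    def test_known_values(self, treated, control, expected):
        res = pks.signed_ks(treated, control)
        assert res.signed_d == pytest.approx(expected)
        assert abs(res.signed_d) == pytest.approx(max(res.d_plus, res.d_minus))

    def test_matches_ecdf_oracle_and_scipy(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n, m = rng.integers(1, 21, size=2)
            t = rng.normal(rng.uniform(-1, 1), 1, n)
            c = rng.normal(0, 1, m)
            if rng.uniform() < 0.3:   # exercise ties
                t = np.round(t)
                c = np.round(c)
            res = pks.signed_ks(t, c)
            assert res.signed_d == pytest.approx(
                brute_force_signed_ks(list(t), list(c)), abs=1e-12)
            assert abs(res.signed_d) == pytest.approx(
                sps.ks_2samp(t, c).statistic, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(a=samples, b=samples)
    def test_swap_antisymmetry(self, a, b):
        fwd = pks.signed_ks(a, b)
        rev = pks.signed_ks(b, a)
        assert fwd.d_plus == pytest.approx(rev.d_minus)
        assert fwd.d_minus == pytest.approx(rev.d_plus)
        if abs(fwd.d_plus - fwd.d_minus) > 1e-9:
            assert fwd.signed_d == pytest.approx(-rev.signed_d)
        else:  # documented tie rule: both directions resolve to +
            assert fwd.signed_d >= 0 and rev.signed_d >= 0

    @settings(derandomize=True, max_examples=100)
    @given(a=samples, b=samples)
    def test_monotone_transform_invariance(self, a, b):
        base = pks.signed_ks(a, b).signed_d
        f = lambda xs: [3.0 * x + np.arctan(x) + 7.0 for x in xs]
        # the transform must stay strictly increasing in float arithmetic
        pooled = sorted(set(a) | set(b))
        assume(len(set(f(pooled))) == len(pooled))
        assert pks.signed_ks(f(a), f(b)).signed_d == pytest.approx(base)

    def test_bounds(self):
        res = pks.signed_ks([0.5], [1.5, 2.5])
        assert 0 <= res.d_plus <= 1 and 0 <= res.d_minus <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            pks.signed_ks([], [1.0])
        with pytest.raises(ValueError):
            pks.signed_ks([1.0], [np.nan])


class TestBootstrapNullStd:
    def test_constant_control_degenerate(self):
        null = pks.bootstrap_null_std([5.0] * 10, n_boot=100, seed=0)
        assert null.std == 0.0 and null.degenerate

    def test_two_point_enumeration_oracle(self):
        # control {0,1}, resample-vs-original: the four equally likely
        # resamples give signed-KS values {-0.5, 0, 0, +0.5}, so the exact
        # SD is sqrt(0.125); the bootstrap estimate at n_boot=1e4 must land
        # within 3 Monte-Carlo standard errors (~0.0053) of it.
        exact_sd = np.sqrt(0.125)
        null = pks.bootstrap_null_std([0.0, 1.0], n_boot=10_000, seed=3,
                                      mode="single")
        assert null.std == pytest.approx(exact_sd, abs=0.0055)

    def test_deterministic_given_seed(self):
        c = np.random.default_rng(1).normal(size=100)
        a = pks.bootstrap_null_std(c, n_boot=500, seed=11)
        b = pks.bootstrap_null_std(c, n_boot=500, seed=11)
        assert a.std == b.std

    def test_monte_carlo_stability(self):
        # estimates at n_boot >= 1000 agree within 5% for n_control >= 200
        c = np.random.default_rng(5).normal(size=300)
        s1 = pks.bootstrap_null_std(c, n_boot=1000, seed=21).std
        s2 = pks.bootstrap_null_std(c, n_boot=2000, seed=22).std
        assert abs(s2 - s1) / s1 < 0.05

    def test_root_n_scaling(self):
        # null KS magnitude ~ n^(-1/2): std(n=2000)/std(n=500) ~ 0.5
        rng = np.random.default_rng(9)
        s_small = pks.bootstrap_null_std(rng.normal(size=500),
                                         n_boot=2000, seed=1).std
        s_large = pks.bootstrap_null_std(rng.normal(size=2000),
                                         n_boot=2000, seed=2).std
        assert s_large / s_small == pytest.approx(0.5, rel=0.2)


class TestZScore:
    def test_identical_samples_zero(self):
        c = list(range(10))
        assert pks.z_score(c, c, 0.1) == 0.0

    def test_arithmetic(self):
        assert pks.z_score([4, 5, 6], [1, 2, 3], 0.1) == pytest.approx(10.0)

    def test_degenerate_std_rejected(self):
        with pytest.raises(ValueError):
            pks.z_score([1, 2], [1, 2], 0.0)


class TestReliabilityFilter:
    def _mat(self, values, descriptors=("d1",)):
        cols = pd.MultiIndex.from_product([descriptors, [0]],
                                          names=["descriptor", "time_min"])
        return pd.DataFrame(np.asarray(values, float).reshape(-1, len(cols)),
                            index=[f"c{i}" for i in range(len(values))],
                            columns=cols)

    def test_perfect_correlation_retained(self):
        z1 = self._mat([1, 2, 3, 4])
        rep = pks.reliability_filter(z1, z1.copy(), threshold=0.4)
        assert rep.table["retained"].all()
        assert rep.table["r"].iloc[0] == pytest.approx(1.0)

    def test_anticorrelation_dropped(self):
        z1 = self._mat([1, 2, 3, 4])
        rep = pks.reliability_filter(z1, -z1, threshold=0.4)
        assert not rep.table["retained"].any()
        assert rep.table["r"].iloc[0] == pytest.approx(-1.0)

    def test_closed_form_pearson(self):
        # rep1=(1,2,3,4), rep2=(1,2,3,0): r = -1/5
        rep = pks.reliability_filter(self._mat([1, 2, 3, 4]),
                                     self._mat([1, 2, 3, 0]), threshold=0.4)
        assert rep.table["r"].iloc[0] == pytest.approx(-0.2)
        assert not rep.table["retained"].iloc[0]

    def test_zero_variance_column_dropped(self):
        z1 = self._mat([[1, 1], [2, 1], [3, 1], [4, 1]], ("d1", "d2"))
        z2 = self._mat([[1, 0], [2, 1], [3, 2], [4, 3]], ("d1", "d2"))
        rep = pks.reliability_filter(z1, z2, threshold=0.4)
        assert rep.dropped_degenerate == [("d2", 0)]
        assert rep.retained == [("d1", 0)]


class TestAssembleZMatrix:
    def _long(self, compounds, descriptors, times, reps=(1,)):
        rows = [{"compound": c, "descriptor": d, "time_min": t,
                 "replicate": r, "z": hash((c, d, t)) % 7 - 3.0}
                for c in compounds for d in descriptors
                for t in times for r in reps]
        return pd.DataFrame(rows)

    def test_single_cell_matrix(self):
        long = self._long(["c1"], ["d1"], [0])
        out = pks.assemble_z_matrix(long, [("d1", 0)], ["c1"], [0])
        assert out.shape == (1, 1)
        assert out.iloc[0, 0] == long["z"].iloc[0]

    def test_replicates_averaged(self):
        long = self._long(["c1"], ["d1"], [0], reps=(1, 2))
        long.loc[long["replicate"] == 2, "z"] += 2.0
        out = pks.assemble_z_matrix(long, [("d1", 0)], ["c1"], [0])
        assert out.iloc[0, 0] == pytest.approx(long["z"].mean())

    def test_missing_cell_raises(self):
        long = self._long(["c1", "c2"], ["d1"], [0])
        long = long[long["compound"] != "c2"]
        with pytest.raises(ValueError, match="incomplete|missing"):
            pks.assemble_z_matrix(long, [("d1", 0)], ["c1", "c2"], [0])

    def test_column_layout(self):
        long = self._long(["c1", "c2"], ["d1", "d2"], [0, 30])
        out = pks.assemble_z_matrix(long, ["d1", "d2"], ["c1", "c2"], [0, 30])
        assert out.shape == (2, 4)
        assert ("d2", 30) in out.columns
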