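"""Percent-change statistics, Mann-Whitney, signature derivation and trends."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from effluxsig.opls import VipResult
from effluxsig.signatures import (
    PercentChangeTable,
    SignatureSet,
    concentration_trend,
    derive_signature,
    mann_whitney_u,
    percent_change_table,
    reference_signatures,
    significance_tier,
)
from effluxsig.simulate import Scenario, generate_dose_series
from effluxsig.peaks import total_sum_normalize
from effluxsig.workflow import analyze_experiment

from conftest import make_table


def enumeration_oracle(a, b):
    """Exact two-sided Mann-Whitney p by enumerating all group labelings."""
    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)

    def u_stat(xs, ys):
        return sum(1 for x in xs for y in ys if x > y) + 0.5 * sum(
            1 for x in xs for y in ys if x == y
        )

    u_obs = u_stat(a, b)
    mean_u = n_a * len(b) / 2
    dev_obs = abs(u_obs - mean_u)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - mean_u) >= dev_obs - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_separated_triples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_multisets_p_one(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_exchangeability(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=5), rng.normal(size=7)
        assert mann_whitney_u(a, b)[1] == pytest.approx(mann_whitney_u(b, a)[1])

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.integers(0, 200), min_size=1, max_size=6),
        b=st.lists(st.integers(0, 200), min_size=1, max_size=6),
    )
    def test_exact_p_matches_enumeration(self, a, b):
        """Tie-free inputs with n<=6 per group agree with the brute-force oracle."""
        pooled = a + b
        if len(set(pooled)) != len(pooled):
            return  # oracle comparison is for the tie-free exact branch
        _, p = mann_whitney_u(a, b)
        assert p == pytest.approx(enumeration_oracle(a, b), abs=1e-12)


class TestPercentChange:
    def _table(self, treated, control):
        vals = np.array(treated + control, dtype=float).reshape(-1, 1)
        t = make_table(vals, groups=["treated"] * len(treated) + ["control"] * len(control),
                       normalized=False)
        return t

    def test_formula(self):
        t = self._table([2.0, 2.0], [1.0, 1.0])
        pct = percent_change_table(t, t.binary_labels())
        assert pct.percent_change("m1") == pytest.approx(100.0)

    def test_no_change_and_halving(self):
        t = self._table([1.0, 1.0], [1.0, 1.0])
        assert percent_change_table(t, t.binary_labels()).percent_change("m1") == 0.0
        t = self._table([0.5, 0.5], [1.0, 1.0])
        assert percent_change_table(t, t.binary_labels()).percent_change("m1") == pytest.approx(-50.0)

    def test_zero_control_marked_undefined(self):
        t = self._table([1.0, 1.0], [0.0, 0.0])
        pct = percent_change_table(t, t.binary_labels())
        assert bool(pct.table.loc["m1", "undefined"])
        assert np.isnan(pct.percent_change("m1"))

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(size=(8, 4))
        t = make_table(x)
        a = percent_change_table(t, t.binary_labels())
        t2 = make_table(x * 37.5)
        b = percent_change_table(t2, t2.binary_labels())
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_tiers(self):
        assert significance_tier(0.2) == "ns"
        assert significance_tier(0.04) == "*"
        assert significance_tier(0.004) == "**"
        assert significance_tier(0.0004) == "***"
        assert significance_tier(0.00004) == "****"


def _pct_from(values: dict[str, float]) -> PercentChangeTable:
    df = pd.DataFrame(
        {
            "percent_change": pd.Series(values),
            "u_statistic": 0.0,
            "p_value": 0.01,
            "p_adjusted": 0.02,
            "tier": "**",
            "undefined": False,
        }
    )
    return PercentChangeTable(table=df)


def _vip_from(values: dict[str, float]) -> VipResult:
    return VipResult(metabolite_ids=list(values), vip=np.array(list(values.values())))


class TestDeriveSignature:
    def _exp(self, pct, vip, kind):
        return (_pct_from(pct), _vip_from(vip), kind)

    def test_requires_both_kinds(self):
        e = self._exp({"a": 10.0}, {"a": 2.0}, "inhibitor")
        with pytest.raises(ValueError, match="knockout"):
            derive_signature([e])

    def test_vip_and_direction_gate(self):
        inh = self._exp({"a": 50.0, "b": 40.0, "c": 30.0}, {"a": 2.0, "b": 2.0, "c": 0.5}, "inhibitor")
        ko = self._exp({"a": 60.0, "b": -20.0, "c": 30.0}, {"a": 1.5, "b": 2.0, "c": 0.5}, "knockout")
        sig = derive_signature([inh, ko], transporter="pgp")
        assert sig.members == [("a", "up")]
        assert sig.excluded["b"].startswith("direction conflict")

    def test_infinite_threshold_empty(self):
        inh = self._exp({"a": 50.0}, {"a": 2.0}, "inhibitor")
        ko = self._exp({"a": 60.0}, {"a": 2.0}, "knockout")
        sig = derive_signature([inh, ko], vip_threshold=np.inf)
        assert sig.members == []

    def test_threshold_is_strict(self):
        inh = self._exp({"a": 50.0}, {"a": 0.75}, "inhibitor")
        ko = self._exp({"a": 60.0}, {"a": 2.0}, "knockout")
        assert derive_signature([inh, ko]).members == []

    def test_order_independence(self):
        e1 = self._exp({"a": 50.0, "b": 10.0}, {"a": 2.0, "b": 1.0}, "inhibitor")
        e2 = self._exp({"a": 60.0, "b": 20.0}, {"a": 1.5, "b": 1.2}, "inhibitor")
        e3 = self._exp({"a": 40.0, "b": 15.0}, {"a": 1.8, "b": 0.9}, "knockout")
        sigs = [derive_signature(list(perm)) for perm in itertools.permutations([e1, e2, e3])]
        assert all(s.members == sigs[0].members for s in sigs)

    def test_down_direction_recorded(self):
        inh = self._exp({"a": -30.0}, {"a": 2.0}, "inhibitor")
        ko = self._exp({"a": -40.0}, {"a": 2.0}, "knockout")
        assert derive_signature([inh, ko]).members == [("a", "down")]


class TestReferenceSignatures:
    def test_published_membership(self):
        sigs = reference_signatures()
        assert len(sigs["pgp"].members) == 11
        assert all(d == "up" for _, d in sigs["pgp"].members)
        assert len(sigs["bcrp"].members) == 4
        assert dict(sigs["bcrp"].members) == {
            "glutamate": "down", "hypoxanthine": "down",
            "xanthine": "down", "pantothenate": "up",
        }
        assert len(sigs["mrp2"].members) == 9
        assert dict(sigs["mrp2"].members)["acetylcarnitine"] == "down"
        assert sum(d == "up" for _, d in sigs["mrp2"].members) == 8

    def test_json_roundtrip(self):
        sig = reference_signatures()["pgp"]
        assert SignatureSet.from_json(sig.to_json()).members == sig.members


class TestConcentrationTrend:
    def test_monotone_series(self):
        tables = [_pct_from({"a": v}) for v in (5.0, 10.0, 20.0, 40.0)]
        rho, p = concentration_trend(tables, "a")
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 24)  # only the two perfect orderings

    def test_constant_series_convention(self):
        tables = [_pct_from({"a": 7.0}) for _ in range(4)]
        assert concentration_trend(tables, "a") == (0.0, 1.0)

    def test_missing_metabolite(self):
        tables = [_pct_from({"a": 1.0})] * 3
        with pytest.raises(KeyError):
            concentration_trend(tables, "zzz")

    def test_needs_three_doses(self):
        with pytest.raises(ValueError):
            concentration_trend([_pct_from({"a": 1.0})] * 2, "a")

    def test_dose_attenuated_generator_series(self):
        scen = Scenario(
            name="dose", transporter="pgp", role="inhibitor",
            effects={"pantothenate": 1.6, "methionine": 1.6},
            noise_cv=0.05, outlier_rate=0.0,
            dose_series=[(0.37, 0.25), (1.1, 0.5), (3.3, 0.75), (10.0, 1.0)],
        )
        series = generate_dose_series(scen, n_metabolites=40, seed=1)
        tables = []
        for _, table, _ in series:
            a = analyze_experiment(table)
            tables.append(a.percent_changes)
        rho, _ = concentration_trend(tables, "pantothenate",
                                     doses=[d for d, _, _ in series])
        assert rho == pytest.approx(1.0)
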