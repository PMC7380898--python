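"""Greedy PS matching vs a brute-force oracle; ASD and balance diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rddmatch import (
    SynthConfig,
    absolute_standardized_difference,
    balance_report,
    fit_propensity,
    generate_panel,
    match_nearest,
    predict_ps,
)
from rddmatch.panel import COVARIATES


def brute_force_match(ps_treated: dict, ps_control: dict, n_matches=1, caliper=None):
    """Independent re-implementation of the greedy rule: treated in descending
    PS (ties by id string), each takes its nearest available control (ties by
    id string), without replacement."""
    pairs, unmatched = [], []
    available = dict(ps_control)
    for t in sorted(ps_treated, key=lambda i: (-ps_treated[i], str(i))):
        got = 0
        for _ in range(n_matches):
            if not available:
                break
            c = min(available, key=lambda i: (abs(available[i] - ps_treated[t]), str(i)))
            if caliper is not None and abs(available[c] - ps_treated[t]) > caliper:
                break
            pairs.append((t, c))
            del available[c]
            got += 1
        if got < n_matches:
            unmatched.append(t)
    return pairs, unmatched


class TestMatchNearest:
    def test_unique_nearest_neighbour(self):
        res = match_nearest(
            pd.Series({"t1": 0.6}), pd.Series({"c1": 0.1, "c2": 0.59})
        )
        assert res.pairs == [("t1", "c2")]
        assert res.unmatched_treated == []

    def test_exact_ps_twins_pair_at_zero_distance(self):
        ps_t = pd.Series({"t1": 0.3, "t2": 0.7})
        ps_c = pd.Series({"c1": 0.3, "c2": 0.7, "c3": 0.5})
        res = match_nearest(ps_t, ps_c)
        assert set(res.pairs) == {("t1", "c1"), ("t2", "c2")}

    def test_nonpositive_caliper_rejected(self):
        with pytest.raises(ValueError, match="caliper"):
            match_nearest(pd.Series({"t": 0.5}), pd.Series({"c": 0.5}), caliper=0.0)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            match_nearest(pd.Series(dtype=float), pd.Series({"c": 0.5}))

    def test_caliper_leaves_distant_treated_unmatched(self):
        res = match_nearest(
            pd.Series({"t1": 0.9, "t2": 0.5}),
            pd.Series({"c1": 0.52, "c2": 0.1}),
            caliper=0.05,
        )
        assert res.pairs == [("t2", "c1")]
        assert res.unmatched_treated == ["t1"]

    def test_one_to_two_matching(self):
        res = match_nearest(
            pd.Series({"t1": 0.5}),
            pd.Series({"c1": 0.45, "c2": 0.52, "c3": 0.9}),
            n_matches=2,
        )
        assert set(res.pairs) == {("t1", "c2"), ("t1", "c1")}

    @given(
        st.integers(1, 10),
        st.integers(1, 20),
        st.integers(0, 2**31 - 1),
        st.sampled_from([None, 0.05, 0.2]),
        st.integers(1, 2),
    )
    @settings(deadline=None, derandomize=True, max_examples=120)
    def test_agrees_with_brute_force_oracle(self, n_t, n_c, seed, caliper, n_matches):
        rng = np.random.default_rng(seed)
        ps_t = pd.Series(rng.random(n_t), index=[f"t{i}" for i in range(n_t)])
        ps_c = pd.Series(rng.random(n_c), index=[f"c{i}" for i in range(n_c)])
        res = match_nearest(ps_t, ps_c, n_matches=n_matches, caliper=caliper)
        exp_pairs, exp_unmatched = brute_force_match(
            ps_t.to_dict(), ps_c.to_dict(), n_matches=n_matches, caliper=caliper
        )
        assert res.pairs == exp_pairs
        assert res.unmatched_treated == exp_unmatched
        # structural invariants: cardinality and no control reuse
        controls = [c for _, c in res.pairs]
        assert len(set(controls)) == len(controls)
        fully = {t for t, _ in res.pairs} - set(res.unmatched_treated)
        assert len(fully) + len(res.unmatched_treated) == len(
            {t for t, _ in res.pairs} | set(res.unmatched_treated)
        )
        assert len(res.pairs) <= n_matches * n_t


class TestASD:
    def test_identical_groups_zero(self):
        assert absolute_standardized_difference([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed_value(self):
        # |3-2| / sqrt((var{2,4} + var{1,3})/2) = 1/sqrt(2)
        val = absolute_standardized_difference([2, 4], [1, 3])
        assert val == pytest.approx(1.0 / np.sqrt(2.0), rel=1e-12)

    def test_symmetric_under_group_exchange(self):
        a, b = [1.0, 2.0, 5.0], [0.5, 2.5, 9.0]
        assert absolute_standardized_difference(a, b) == pytest.approx(
            absolute_standardized_difference(b, a)
        )

    @given(st.floats(0.01, 100.0))
    @settings(deadline=None, derandomize=True)
    def test_scale_invariance(self, c):
        a = np.array([1.0, 2.0, 4.0])
        b = np.array([2.0, 3.0, 7.0])
        assert absolute_standardized_difference(c * a, c * b) == pytest.approx(
            absolute_standardized_difference(a, b), rel=1e-9
        )

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            absolute_standardized_difference([2.0, 2.0], [2.0, 2.0])


@pytest.fixture(scope="module")
def matched(small_panel):
    m0 = small_panel.month0()
    model = fit_propensity(m0[COVARIATES], m0["treated"].to_numpy())
    ps = pd.Series(predict_ps(model, m0[COVARIATES]), index=m0.index)
    match = match_nearest(
        ps.loc[small_panel.treated_ids()], ps.loc[small_panel.control_ids()]
    )
    return ps, match


class TestBalanceReport:

    def test_matching_improves_mean_balance(self, small_panel, matched):
        ps, match = matched
        rep = balance_report(small_panel, ps, match)
        assert rep.mean_asd_after < rep.mean_asd_before
        assert set(rep.table["covariate"]) == set(COVARIATES) | {"ps"}
        assert (rep.table["asd_before"] >= 0).all()
        assert (rep.table["asd_after"] >= 0).all()

    def test_unknown_pair_rejected(self, small_panel, matched):
        ps, match = matched
        bad = type(match)(
            pairs=match.pairs + [("ghost", "phantom")],
            n_matches_per_treated=1, caliper=None, unmatched_treated=[],
        )
        with pytest.raises(ValueError, match="unknown physician"):
            balance_report(small_panel, ps, bad)

    def test_self_match_gives_zero_asd(self):
        """Control pool that is an exact copy of the treated arm: after
        matching every ASD is 0 (up to the PS ties ordering)."""
        panel = generate_panel(SynthConfig(n_treated=20, n_control_pool=80, seed=13))
        m0 = panel.month0()
        treated = m0[m0["treated"] == 1]
        clone = panel.df[panel.df["treated"] == 1].copy()
        clone["physician_id"] = "copy_" + clone["physician_id"]
        clone["treated"] = 0
        from rddmatch import PhysicianPanel

        twin = PhysicianPanel(
            pd.concat(
                [panel.df[panel.df["treated"] == 1], clone], ignore_index=True
            ),
            panel.cutoff_index,
        )
        m0t = twin.month0()
        # a fixed injective score (identical for clones); a fitted model would
        # be exactly intercept-only here, making the PS degenerate by design
        eta = 0.01 * m0t["thank"] + 0.3 * m0t["prs"] + 0.05 * m0t["article"]
        ps = 1.0 / (1.0 + np.exp(-(eta - eta.mean())))
        match = match_nearest(ps.loc[twin.treated_ids()], ps.loc[twin.control_ids()])
        rep = balance_report(twin, ps, match)
        assert rep.mean_asd_after == pytest.approx(0.0, abs=1e-8)
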