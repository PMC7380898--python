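"""Nearest-neighbour propensity-score matching and covariate balance.

Controls are matched to treated physicians 1:1 (generalizable to 1:N) by
greedy nearest-neighbour on the propensity score, without replacement.
Treated units are processed in descending PS order (hardest to match first);
among equidistant controls the lowest identifier wins, so the pairing is a
deterministic function of the inputs. Balance before and after matching is
quantified with the absolute standardized difference (ASD): the absolute
difference of group means over the square root of the average of the two
sample variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import COVARIATES, PhysicianPanel


@dataclass
class MatchResult:
    """A treated-to-control pairing.

    ``pairs`` lists (treated_id, control_id) tuples; with ``n_matches`` > 1 a
    treated id appears once per matched control. Controls are never reused.
    """

    pairs: list[tuple]
    n_matches_per_treated: int
    caliper: float | None
    unmatched_treated: list

    @property
    def matched_control_ids(self) -> list:
        return [c for _, c in self.pairs]

    @property
    def matched_treated_ids(self) -> list:
        return sorted({t for t, _ in self.pairs})

    def to_csv(self, path) -> None:
        pd.DataFrame(self.pairs, columns=["treated_id", "control_id"]).to_csv(
            path, index=False
        )


@dataclass
class BalanceReport:
    """Per-covariate ASD before and after matching, with the group moments."""

    table: pd.DataFrame  # columns: covariate, asd_before, asd_after, means/vars

    def _covariate_rows(self) -> pd.DataFrame:
        # summary means are over the covariates proper; the PS row stays in
        # the table as its own diagnostic
        return self.table[self.table["covariate"] != "ps"]

    @property
    def mean_asd_before(self) -> float:
        return float(self._covariate_rows()["asd_before"].mean())

    @property
    def mean_asd_after(self) -> float:
        return float(self._covariate_rows()["asd_after"].mean())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def absolute_standardized_difference(x_treat, x_control) -> float:
    """|mean(x_treat) - mean(x_control)| / sqrt((s2_treat + s2_control) / 2).

    Sample variances use the n-1 denominator. The statistic is unit-free,
    symmetric under group exchange and invariant to rescaling both groups.
    """
    xt = np.asarray(x_treat, dtype=float)
    xc = np.asarray(x_control, dtype=float)
    if xt.size < 2 or xc.size < 2:
        raise ValueError("each group needs at least 2 values")
    s2t = xt.var(ddof=1)
    s2c = xc.var(ddof=1)
    pooled = (s2t + s2c) / 2.0
    if pooled <= 0.0:
        raise ValueError(
            "zero pooled variance: covariate is constant in both groups"
        )
    return float(abs(xt.mean() - xc.mean()) / np.sqrt(pooled))


def match_nearest(
    ps_treated: pd.Series,
    ps_control: pd.Series,
    n_matches: int = 1,
    caliper: float | None = None,
) -> MatchResult:
    """Greedy nearest-available-neighbour matching without replacement.

    Parameters
    ----------
    ps_treated, ps_control : Series
        Propensity scores indexed by physician identifier.
    n_matches : int
        Controls matched per treated unit (default 1, i.e. one-to-one).
    caliper : float, optional
        Maximum allowed |PS_treated - PS_control| for a valid pair. A treated
        unit whose nearest available control lies outside the caliper stays
        (partially) unmatched.
    """
    if len(ps_treated) == 0 or len(ps_control) == 0:
        raise ValueError("treated and control propensity-score sets must be non-empty")
    if caliper is not None and caliper <= 0:
        raise ValueError("caliper must be > 0 (or None for no caliper)")
    if n_matches < 1:
        raise ValueError("n_matches must be >= 1")

    # deterministic order: descending PS, ties by identifier
    t_order = sorted(ps_treated.index, key=lambda i: (-ps_treated[i], str(i)))
    c_ids = np.array(sorted(ps_control.index, key=str), dtype=object)
    c_ps = np.array([ps_control[i] for i in c_ids], dtype=float)
    available = np.ones(len(c_ids), dtype=bool)

    pairs: list[tuple] = []
    unmatched: list = []
    for t in t_order:
        got = 0
        for _ in range(n_matches):
            if not available.any():
                break
            dist = np.abs(c_ps - ps_treated[t])
            dist[~available] = np.inf
            j = int(np.argmin(dist))  # ties: first index = lowest identifier
            if caliper is not None and dist[j] > caliper:
                break
            pairs.append((t, c_ids[j]))
            available[j] = False
            got += 1
        if got < n_matches:
            unmatched.append(t)

    return MatchResult(
        pairs=pairs,
        n_matches_per_treated=n_matches,
        caliper=caliper,
        unmatched_treated=unmatched,
    )


def balance_report(
    panel: PhysicianPanel, ps: pd.Series, match: MatchResult
) -> BalanceReport:
    """ASD for the five covariates and the PS itself, before vs after matching.

    'Before' compares treated physicians with the full control pool; 'after'
    compares them with the matched controls only. Covariates are the month-0
    cumulative snapshot.
    """
    m0 = panel.month0()
    known = set(m0.index)
    for t, c in match.pairs:
        if t not in known or c not in known:
            raise ValueError(f"match pair ({t!r}, {c!r}) references unknown physician")

    t_ids = list(panel.treated_ids())
    pool_ids = list(panel.control_ids())
    matched_ids = match.matched_control_ids

    rows = []
    for name in COVARIATES + ["ps"]:
        if name == "ps":
            vt = ps.loc[t_ids].to_numpy()
            vpool = ps.loc[pool_ids].to_numpy()
            vmatch = ps.loc[matched_ids].to_numpy()
        else:
            vt = m0.loc[t_ids, name].to_numpy()
            vpool = m0.loc[pool_ids, name].to_numpy()
            vmatch = m0.loc[matched_ids, name].to_numpy()
        rows.append(
            {
                "covariate": name,
                "asd_before": absolute_standardized_difference(vt, vpool),
                "asd_after": absolute_standardized_difference(vt, vmatch),
                "mean_treated": float(np.mean(vt)),
                "mean_pool": float(np.mean(vpool)),
                "mean_matched": float(np.mean(vmatch)),
                "var_treated": float(np.var(vt, ddof=1)),
                "var_pool": float(np.var(vpool, ddof=1)),
                "var_matched": float(np.var(vmatch, ddof=1)),
            }
        )
    return BalanceReport(table=pd.DataFrame(rows))
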