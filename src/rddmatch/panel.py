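"""Physician-month panel container, CSV round trip and schema validation.

The panel is long-format: one row per physician per month. Month 0 carries the
cumulative state of every variable at the start of the observation window; the
remaining months carry marginal (per-month) changes. Covariate marginals may be
negative (ratings can drop); outcome marginals are monthly counts and must be
non-negative. ``treated`` is constant within a physician and ``post`` flags the
months at or after the award cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: five pre-treatment covariates, in canonical column order
COVARIATES = ["prs", "thank", "gift", "contr", "article"]
#: the two service-volume outcomes
OUTCOMES = ["patients", "views"]

PANEL_COLUMNS = ["physician_id", "month_index"] + COVARIATES + OUTCOMES + ["treated", "post"]

N_MONTHS = 12


class PanelValidationError(ValueError):
    """Raised when a panel violates its schema; carries the itemized failures."""

    def __init__(self, failures: list[str]):
        self.failures = failures
        super().__init__("panel validation failed:\n  - " + "\n  - ".join(failures))


@dataclass
class PhysicianPanel:
    """A balanced 12-month physician panel.

    Parameters
    ----------
    df : pandas.DataFrame
        Long-format table with columns :data:`PANEL_COLUMNS`.
    cutoff_index : int
        First post-award month (default 6, the January analogue in a
        July-to-June window).
    """

    df: pd.DataFrame
    cutoff_index: int = 6

    @property
    def n_physicians(self) -> int:
        return self.df["physician_id"].nunique()

    @property
    def physician_ids(self) -> np.ndarray:
        return self.df["physician_id"].unique()

    def month0(self) -> pd.DataFrame:
        """The month-0 snapshot (cumulative initial state), one row per physician."""
        return self.df[self.df["month_index"] == 0].set_index("physician_id")

    def monthly(self) -> pd.DataFrame:
        """Months 1..11 — the marginal-change rows used for estimation."""
        return self.df[self.df["month_index"] > 0]

    def treated_ids(self) -> np.ndarray:
        m0 = self.month0()
        return m0.index[m0["treated"] == 1].to_numpy()

    def control_ids(self) -> np.ndarray:
        m0 = self.month0()
        return m0.index[m0["treated"] == 0].to_numpy()

    def outcome_series(self, outcome: str, ids=None) -> pd.DataFrame:
        """Long series (physician_id, month_index, value) for one outcome,
        months 1..11, optionally restricted to a set of physicians."""
        if outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
        sub = self.monthly()
        if ids is not None:
            sub = sub[sub["physician_id"].isin(np.asarray(ids))]
        return sub[["physician_id", "month_index", outcome]].rename(columns={outcome: "value"})

    def subset(self, ids) -> "PhysicianPanel":
        mask = self.df["physician_id"].isin(np.asarray(ids))
        return PhysicianPanel(self.df[mask].reset_index(drop=True), self.cutoff_index)

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, encoding="utf-8")

    @classmethod
    def from_csv(cls, path, cutoff_index: int = 6) -> "PhysicianPanel":
        df = pd.read_csv(path, encoding="utf-8")
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise PanelValidationError([f"missing columns: {missing}"])
        return cls(df[PANEL_COLUMNS].copy(), cutoff_index)

    def validate(self) -> list[str]:
        """Check every schema invariant; return the list of failures (empty = pass)."""
        return validate_panel(self)


def validate_panel(panel: PhysicianPanel) -> list[str]:
    """Itemized schema validation of a :class:`PhysicianPanel`.

    Rules checked, in order: required columns present; every physician has
    exactly one record for each month 0..11; ``treated`` binary and constant
    within physician; ``post`` binary and equal to ``month_index >= cutoff``;
    outcome marginals non-negative; month-0 state non-negative with the rating
    score inside [0, 5].
    """
    df = panel.df
    failures: list[str] = []

    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        return [f"missing columns: {missing}"]

    months = df.groupby("physician_id")["month_index"]
    bad_shape = months.apply(lambda m: sorted(m) != list(range(N_MONTHS)))
    if bad_shape.any():
        offenders = bad_shape.index[bad_shape].tolist()[:5]
        failures.append(
            f"unbalanced panel: physicians without exactly one record per month 0-11: {offenders}"
        )

    if not df["treated"].isin([0, 1]).all():
        failures.append("treated flag not binary")
    else:
        varying = df.groupby("physician_id")["treated"].nunique()
        offenders = varying.index[varying > 1].tolist()[:5]
        if offenders:
            failures.append(f"treated flag varies within physician: {offenders}")

    if not df["post"].isin([0, 1]).all():
        failures.append("post flag not binary")
    else:
        expected = (df["month_index"] >= panel.cutoff_index).astype(int)
        if not (df["post"] == expected).all():
            failures.append(
                f"post flag inconsistent with cutoff_index={panel.cutoff_index}"
            )

    for col in OUTCOMES:
        if (df[col] < 0).any():
            failures.append(f"negative values in outcome {col!r}")

    m0 = df[df["month_index"] == 0]
    for col in COVARIATES + OUTCOMES:
        if (m0[col] < 0).any():
            failures.append(f"negative month-0 state in {col!r}")
    if ((m0["prs"] < 0) | (m0["prs"] > 5)).any():
        failures.append("month-0 rating score outside [0, 5]")

    return failures


def marginal_changes(cumulative: np.ndarray | pd.Series | list) -> np.ndarray:
    """Convert a cumulative series to [initial state, marginal changes].

    Output position 0 is the initial cumulative state; position ``t`` (t >= 1)
    is ``cumulative[t] - cumulative[t-1]``. Summing the marginals back onto the
    initial state reconstructs the cumulative series exactly. A non-monotone
    cumulative count series produces negative marginals, which is reported as a
    warning (ratings legitimately decline) rather than an error.
    """
    arr = np.asarray(cumulative, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("cumulative series needs at least 2 time points")
    out = np.empty_like(arr)
    out[0] = arr[0]
    out[1:] = np.diff(arr)
    if (out[1:] < 0).any():
        warnings.warn(
            "non-monotone cumulative series: negative marginal change(s) produced",
            stacklevel=2,
        )
    return out


def cumulative_from_marginals(marginals: np.ndarray | list) -> np.ndarray:
    """Inverse of :func:`marginal_changes` (initial state + cumulative sums)."""
    arr = np.asarray(marginals, dtype=float)
    return np.cumsum(arr)
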