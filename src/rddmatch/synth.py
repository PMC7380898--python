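"""Seeded synthetic physician-month panels.

The generator emulates the statistical structure a matched regression-
discontinuity study of a physician incentive assumes: a cross-section of
physicians with five heavy-tailed profile covariates, treatment (an honorary
title) assigned by thresholding a noisy weighted covariate score (selection on
observables, so the true assignment probability is exactly logistic in the
covariates), twelve monthly records per physician of which month 0 is the
cumulative initial state and months 1-11 are marginal changes, and an additive
level jump in the treated group's monthly outcomes starting at the award
cutoff, optionally delayed by a lag.

Exact group sizes are obtained by quota (case-control) sampling: candidate
physicians are drawn from the covariate law and Bernoulli-assigned by the
logistic rule until both arms are full. Within the pooled sample the logistic
slopes on the covariates are unchanged by this sampling; only the intercept
absorbs the sampling odds, which is why :meth:`SynthConfig.implied_logit_slopes`
exposes slopes, not an intercept.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .panel import COVARIATES, N_MONTHS, PhysicianPanel

# Covariate generating law: prs ~ clipped Normal, the four count/score
# covariates ~ log-normal (right-skewed, like real profile statistics).
# (log_mean, sigma) for log-normals; (mean, sd) for prs.
_PRS_MEAN, _PRS_SD = 4.5, 0.25
_LOGNORMAL_PARAMS = {
    "thank": (math.log(110.0), 0.6),
    "gift": (math.log(550.0), 0.7),
    "contr": (math.log(70000.0), 0.5),
    "article": (math.log(45.0), 0.8),
}


def _covariate_moments() -> dict[str, tuple[float, float]]:
    """Theoretical (mean, sd) of each covariate under the generating law."""
    moments = {"prs": (_PRS_MEAN, _PRS_SD)}
    for name, (mu, sig) in _LOGNORMAL_PARAMS.items():
        m = math.exp(mu + sig**2 / 2.0)
        s = m * math.sqrt(math.expm1(sig**2))
        moments[name] = (m, s)
    return moments


COVARIATE_MOMENTS = _covariate_moments()

# Monthly covariate drift laws for months 1-11 (marginal changes). Magnitudes
# are loosely sized on real monthly profile statistics; they are plumbing, not
# claims. prs drift can be negative (ratings decline).
_DRIFT = {
    "prs": ("normal", 0.004, 0.008),
    "thank": ("poisson", 5.0),
    "gift": ("poisson", 18.0),
    "contr": ("normal", 3000.0, 600.0),
    "article": ("poisson", 1.2),
}


@dataclass
class SynthConfig:
    """Full data-generating-process specification for the synthetic panel.

    Defaults are the study conditions: 346 treated physicians against a pool
    of 3000, award cutoff at month 6 of a 12-month window, an additive jump of
    80 000 monthly home-page views and 20 monthly consultations for treated
    physicians, no lag.
    """

    n_treated: int = 346
    n_control_pool: int = 3000
    cutoff_index: int = 6
    score_weights: dict[str, float] = field(
        default_factory=lambda: {
            "prs": 0.8, "thank": 0.6, "gift": 0.4, "contr": 0.6, "article": 0.3
        }
    )
    score_threshold: float = 2.5
    jump_patients: float = 20.0
    jump_views: float = 80000.0
    lag_months: int = 0
    pre_trend_patients: float = -3.0
    pre_trend_views: float = -4000.0
    base_patients: float = 160.0
    base_views: float = 170000.0
    physician_effect_sd: float = 0.3
    confound_strength: float = 0.25
    dispersion_patients: float = 0.15
    dispersion_views: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control_pool < self.n_treated:
            raise ValueError(
                "infeasible config: n_control_pool < n_treated "
                f"({self.n_control_pool} < {self.n_treated}); 1:1 matching needs "
                "a control pool at least as large as the treated group"
            )
        if not 1 <= self.cutoff_index <= 11:
            raise ValueError(f"cutoff_index must be in 1..11, got {self.cutoff_index}")
        if self.lag_months < 0:
            raise ValueError("lag_months must be >= 0")
        if self.lag_months + self.cutoff_index > 11:
            raise ValueError(
                "infeasible config: lag_months + cutoff_index > 11 "
                f"({self.lag_months} + {self.cutoff_index}); the lagged jump would "
                "fall outside the observation window"
            )
        missing = [c for c in COVARIATES if c not in self.score_weights]
        if missing:
            raise ValueError(f"score_weights missing covariates: {missing}")

    def implied_logit_slopes(self) -> dict[str, float]:
        """Logistic-regression slopes on the *raw* covariate scale implied by
        the standardized score weights: weight / sd(covariate)."""
        return {
            c: self.score_weights[c] / COVARIATE_MOMENTS[c][1] for c in COVARIATES
        }

    # -- flat key-value serialization -------------------------------------

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        weights = d.pop("score_weights")
        for c, w in weights.items():
            d[f"score_weight_{c}"] = w
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        weights = {}
        for c in COVARIATES:
            key = f"score_weight_{c}"
            if key in d:
                weights[c] = float(d.pop(key))
        if weights:
            d["score_weights"] = weights
        return cls(**d)


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    cov = {
        "prs": np.clip(rng.normal(_PRS_MEAN, _PRS_SD, n), 0.0, 5.0),
    }
    for name, (mu, sig) in _LOGNORMAL_PARAMS.items():
        draw = rng.lognormal(mu, sig, n)
        if name != "contr":  # counts are integers; contribution score is a real
            draw = np.round(draw)
        cov[name] = draw
    return pd.DataFrame(cov)


def _standardized_score(cov: pd.DataFrame, weights: dict[str, float]) -> np.ndarray:
    score = np.zeros(len(cov))
    for c in COVARIATES:
        mean, sd = COVARIATE_MOMENTS[c]
        score += weights[c] * (cov[c].to_numpy() - mean) / sd
    return score


def generate_panel(config: SynthConfig) -> PhysicianPanel:
    """Generate a balanced 12-month panel under ``config``.

    A pure function of the config: the same config (including seed) always
    yields an identical panel. The returned panel has exactly
    ``config.n_treated`` treated physicians and ``config.n_control_pool``
    controls, with the treated arm's monthly outcomes raised by the configured
    jumps from month ``cutoff_index + lag_months`` onwards.
    """
    rng = np.random.default_rng(config.seed)

    # quota sampling: draw candidates, assign by the logistic rule, fill arms
    cov_parts, score_parts, treat_parts = [], [], []
    n_t = n_c = 0
    batch = max(1024, 2 * (config.n_treated + config.n_control_pool))
    for _ in range(1000):
        cands = _draw_covariates(rng, batch)
        score = _standardized_score(cands, config.score_weights)
        noise = rng.logistic(0.0, 1.0, batch)
        assigned = (score + noise > config.score_threshold).astype(int)
        cov_parts.append(cands)
        score_parts.append(score)
        treat_parts.append(assigned)
        n_t += int(assigned.sum())
        n_c += int((1 - assigned).sum())
        if n_t >= config.n_treated and n_c >= config.n_control_pool:
            break
    else:  # pragma: no cover - defensive; the logistic tail is never this thin
        raise RuntimeError("quota sampling failed to fill both arms")

    cov = pd.concat(cov_parts, ignore_index=True)
    score = np.concatenate(score_parts)
    assigned = np.concatenate(treat_parts)
    t_idx = np.flatnonzero(assigned == 1)[: config.n_treated]
    c_idx = np.flatnonzero(assigned == 0)[: config.n_control_pool]
    keep = np.concatenate([t_idx, c_idx])
    cov = cov.iloc[keep].reset_index(drop=True)
    score = score[keep]
    treated = np.concatenate(
        [np.ones(config.n_treated, int), np.zeros(config.n_control_pool, int)]
    )

    n = len(cov)
    ids = np.array([f"phys_{i:05d}" for i in range(n)])

    # physician-level outcome heterogeneity: a mean-one log-normal random
    # intercept per outcome, plus level confounding with the selection score
    # (selected physicians are busier) - motivates matching and clustered SEs
    def _level_multiplier(sd: float) -> np.ndarray:
        re = np.exp(rng.normal(0.0, sd, n) - sd**2 / 2.0)
        conf = np.exp(
            config.confound_strength * score
            - config.confound_strength**2 * np.var(score) / 2.0
        )
        return re * conf

    mult_p = _level_multiplier(config.physician_effect_sd)
    mult_v = _level_multiplier(config.physician_effect_sd)

    months = np.arange(1, N_MONTHS)
    jump_start = config.cutoff_index + config.lag_months
    jump_on = (months >= jump_start).astype(float)  # (11,)

    # mean monthly consultations / views per physician-month, additive jump
    mu_p = np.maximum(
        config.base_patients * mult_p[:, None]
        + config.pre_trend_patients * (months - 1)[None, :],
        5.0,
    ) + config.jump_patients * treated[:, None] * jump_on[None, :]
    mu_v = np.maximum(
        config.base_views * mult_v[:, None]
        + config.pre_trend_views * (months - 1)[None, :],
        1000.0,
    ) + config.jump_views * treated[:, None] * jump_on[None, :]

    # consultations: gamma-Poisson mixture (negative-binomial-type) around mu
    d = config.dispersion_patients
    if d > 0:
        lam = rng.gamma(1.0 / d**2, d**2 * mu_p)
    else:
        lam = mu_p
    patients = rng.poisson(lam).astype(float)
    # views: mean-corrected log-normal noise around mu (heavy right tail)
    s = config.dispersion_views
    views = np.round(mu_v * np.exp(rng.normal(0.0, s, mu_v.shape) - s**2 / 2.0))

    # month-0 cumulative outcome states (descriptive only; not estimated on)
    patients0 = np.round(rng.lognormal(math.log(5500.0), 0.6, n))
    views0 = np.round(rng.lognormal(math.log(4.0e6), 0.7, n))

    # covariate marginal drifts for months 1-11
    drift = {}
    for name, spec_ in _DRIFT.items():
        if spec_[0] == "poisson":
            drift[name] = rng.poisson(spec_[1], (n, N_MONTHS - 1)).astype(float)
        else:
            draw = rng.normal(spec_[1], spec_[2], (n, N_MONTHS - 1))
            if name == "contr":
                draw = np.maximum(np.round(draw), 0.0)
            drift[name] = draw

    rows = {
        "physician_id": np.repeat(ids, N_MONTHS),
        "month_index": np.tile(np.arange(N_MONTHS), n),
    }
    for c in COVARIATES:
        block = np.column_stack([cov[c].to_numpy(), drift[c]])
        rows[c] = block.ravel()
    rows["patients"] = np.column_stack([patients0, patients]).ravel()
    rows["views"] = np.column_stack([views0, views]).ravel()
    rows["treated"] = np.repeat(treated, N_MONTHS)
    rows["post"] = np.tile(
        (np.arange(N_MONTHS) >= config.cutoff_index).astype(int), n
    )
    df = pd.DataFrame(rows)
    return PhysicianPanel(df, cutoff_index=config.cutoff_index)
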