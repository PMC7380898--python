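"""End-to-end analysis pipeline.

Stages, in causal order: obtain the panel (simulate or load), validate the
schema, fit the propensity model on the month-0 covariate snapshot, match
controls to treated physicians, report covariate balance, estimate the
group-wise discontinuities at the cutoff for both outcomes with both
estimators, form the differential effects, and scan for lagged
discontinuities. Every number in the resulting report is a deterministic
function of the configuration (including the seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .matching import BalanceReport, MatchResult, balance_report, match_nearest
from .panel import COVARIATES, OUTCOMES, PanelValidationError, PhysicianPanel
from .propensity import PropensityModel, fit_propensity, predict_ps
from .rdd import (
    DifferentialEffect,
    RDDFit,
    differential_effect,
    fit_local_linear_rdd,
    fit_parametric_rdd,
    results_table,
    scan_lag,
)
from .synth import SynthConfig, generate_panel

log = logging.getLogger("rddmatch")

_PIPELINE_KEYS = (
    "panel_csv", "cutoff_index", "n_matches", "caliper", "polynomial_order",
    "bandwidth_months", "kernel", "max_lag", "log1p_counts", "output_dir",
    "seed", "log_level",
)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one full run.

    Exactly one of ``panel_csv`` (a pre-existing panel file) and ``synth``
    (a synthetic data-generating process) must be provided.
    """

    panel_csv: str | None = None
    synth: SynthConfig | None = None
    cutoff_index: int = 6
    n_matches: int = 1
    caliper: float | None = None
    polynomial_order: int = 1
    bandwidth_months: float = 3.0
    kernel: str = "triangular"
    max_lag: int = 3
    log1p_counts: bool = False
    output_dir: str | None = None
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.panel_csv is None) == (self.synth is None):
            raise ValueError(
                "exactly one of panel_csv and synth must be provided"
            )
        if self.synth is not None:
            if self.seed is not None:
                self.synth = dataclasses.replace(self.synth, seed=self.seed)
            self.cutoff_index = self.synth.cutoff_index

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in _PIPELINE_KEYS}
        if self.synth is not None:
            for k, v in dataclasses.asdict(self.synth).items():
                if k == "score_weights":
                    for c, w in v.items():
                        d[f"score_weight_{c}"] = w
                else:
                    d[f"synth_{k}"] = v
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        synth_kwargs = {}
        weights = {}
        for k in list(d):
            if k.startswith("synth_"):
                synth_kwargs[k[len("synth_"):]] = d.pop(k)
            elif k.startswith("score_weight_"):
                weights[k[len("score_weight_"):]] = float(d.pop(k))
        if weights:
            synth_kwargs["score_weights"] = weights
        synth = SynthConfig(**synth_kwargs) if synth_kwargs else None
        kwargs = {k: d[k] for k in _PIPELINE_KEYS if k in d}
        return cls(synth=synth, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """All pipeline outputs plus the provenance needed to regenerate them."""

    propensity: PropensityModel
    balance: BalanceReport
    match: MatchResult
    fits: list[RDDFit]
    differentials: list[DifferentialEffect]
    lag_profiles: dict[str, tuple[list[RDDFit], int]]
    provenance: dict

    def fit(self, group: str, outcome: str, method: str) -> RDDFit:
        for f in self.fits:
            if (f.group, f.outcome, f.method) == (group, outcome, method):
                return f
        raise KeyError((group, outcome, method))

    def differential(self, outcome: str, method: str) -> DifferentialEffect:
        for d in self.differentials:
            if (d.outcome, d.method) == (outcome, method):
                return d
        raise KeyError((outcome, method))

    def best_lag(self, outcome: str) -> int:
        return self.lag_profiles[outcome][1]

    def summary_text(self) -> str:
        lines = [
            f"rddmatch run {self.provenance['config_hash']} "
            f"(seed={self.provenance['seed']}, v{self.provenance['version']})",
            "",
            f"propensity fit: converged={self.propensity.converged} "
            f"({self.propensity.n_iterations} iterations, "
            f"logL={self.propensity.log_likelihood:.2f})",
            f"matched pairs: {len(self.match.pairs)} "
            f"(unmatched treated: {len(self.match.unmatched_treated)})",
            f"mean covariate ASD: {self.balance.mean_asd_before:.3f} before -> "
            f"{self.balance.mean_asd_after:.3f} after matching",
            "",
            "discontinuity estimates at the cutoff:",
        ]
        for f in self.fits:
            lines.append(
                f"  {f.outcome:8s} {f.group:8s} {f.method:13s} "
                f"jump={f.estimate:12.3f}  SE={f.std_error:10.3f}  "
                f"N={f.n_obs}  p={f.p_value:.3g}"
            )
        lines.append("")
        lines.append("differential (treated - control) effects:")
        for d in self.differentials:
            lines.append(
                f"  {d.outcome:8s} {d.method:13s} "
                f"estimate={d.estimate:12.3f}  SE={d.std_error:10.3f}  "
                f"p={d.p_value:.3g}"
            )
        lines.append("")
        for outcome, (profile, best) in self.lag_profiles.items():
            zs = ", ".join(
                f"lag {i}: |z|={abs(f.estimate) / f.std_error if f.std_error else float('inf'):.2f}"
                for i, f in enumerate(profile)
            )
            lines.append(f"lag scan ({outcome}): best lag = {best}  [{zs}]")
        return "\n".join(lines)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full matched-RDD analysis described by ``config``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    t0 = time.perf_counter()

    if config.synth is not None:
        panel = generate_panel(config.synth)
        log.info("stage=simulate n_physicians=%d", panel.n_physicians)
    else:
        panel = PhysicianPanel.from_csv(config.panel_csv, config.cutoff_index)
        log.info("stage=load n_physicians=%d", panel.n_physicians)

    failures = panel.validate()
    if failures:
        raise PanelValidationError(failures)
    log.info("stage=validate ok=%d rules", 1)

    m0 = panel.month0()
    model = fit_propensity(
        m0[COVARIATES], m0["treated"].to_numpy(), log1p_counts=config.log1p_counts
    )
    ps = pd.Series(
        predict_ps(model, m0[COVARIATES], log1p_counts=config.log1p_counts),
        index=m0.index,
    )
    log.info(
        "stage=propensity converged=%s iterations=%d",
        model.converged, model.n_iterations,
    )

    t_ids = panel.treated_ids()
    c_ids = panel.control_ids()
    match = match_nearest(
        ps.loc[t_ids], ps.loc[c_ids],
        n_matches=config.n_matches, caliper=config.caliper,
    )
    log.info("stage=match pairs=%d unmatched=%d",
             len(match.pairs), len(match.unmatched_treated))

    balance = balance_report(panel, ps, match)
    log.info("stage=balance mean_asd %.3f -> %.3f",
             balance.mean_asd_before, balance.mean_asd_after)

    # estimation sample: all treated plus matched controls only
    groups = {"treated": list(t_ids), "control": match.matched_control_ids}
    fits: list[RDDFit] = []
    for outcome in OUTCOMES:
        for gname, ids in groups.items():
            series = panel.outcome_series(outcome, ids)
            fits.append(
                fit_parametric_rdd(
                    series, panel.cutoff_index,
                    polynomial_order=config.polynomial_order,
                    group=gname, outcome=outcome,
                )
            )
            fits.append(
                fit_local_linear_rdd(
                    series, panel.cutoff_index,
                    bandwidth_months=config.bandwidth_months,
                    kernel=config.kernel,
                    group=gname, outcome=outcome,
                )
            )
    log.info("stage=rdd fits=%d", len(fits))

    diffs = []
    for outcome in OUTCOMES:
        for method in ("parametric", "nonparametric"):
            tf = next(f for f in fits
                      if (f.group, f.outcome, f.method) == ("treated", outcome, method))
            cf = next(f for f in fits
                      if (f.group, f.outcome, f.method) == ("control", outcome, method))
            diffs.append(differential_effect(tf, cf))

    lag_profiles = {}
    for outcome in OUTCOMES:
        series = panel.outcome_series(outcome, groups["treated"])
        lag_profiles[outcome] = scan_lag(
            series, panel.cutoff_index, config.max_lag,
            method="parametric", polynomial_order=config.polynomial_order,
            group="treated", outcome=outcome,
        )
    log.info("stage=lag_scan outcomes=%d wall=%.2fs",
             len(lag_profiles), time.perf_counter() - t0)

    report = RunReport(
        propensity=model,
        balance=balance,
        match=match,
        fits=fits,
        differentials=diffs,
        lag_profiles=lag_profiles,
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed if config.seed is not None
            else (config.synth.seed if config.synth else None),
            "version": __version__,
        },
    )

    if config.output_dir is not None:
        _write_artifacts(config, panel, report)
    return report


def _write_artifacts(config: PipelineConfig, panel: PhysicianPanel,
                     report: RunReport) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.synth is not None:
        panel.to_csv(out / "panel.csv")
    report.match.to_csv(out / "matches.csv")
    report.balance.to_csv(out / "balance.csv")
    results_table(report.fits).to_csv(out / "rdd_results.csv", index=False)
    diff_df = pd.DataFrame(
        [dataclasses.asdict(d) for d in report.differentials]
    )
    diff_df.to_csv(out / "differential_effects.csv", index=False)
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    (out / "report.txt").write_text(report.summary_text() + "\n", encoding="utf-8")
    log.info("stage=write output_dir=%s", out)
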