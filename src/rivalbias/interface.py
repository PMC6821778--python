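"""Pipeline orchestration: configuration, logging, CLI.

A run executes the enabled stages in order — simulate (or load user CSVs),
preprocess, fit, evidence, classical — writing every intermediate product as
CSV into the output directory together with the resolved configuration and a
timed log, so a finished run can be reproduced bit-identically from its
archived config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import classical, evidence, hierfit, preprocess, simulate

log = logging.getLogger("rivalbias")

STAGES = ("simulate", "preprocess", "fit", "evidence", "classical")


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    cohort: simulate.CohortConfig = field(default_factory=simulate.CohortConfig)
    prior: hierfit.PriorSpec = field(default_factory=hierfit.PriorSpec)
    mcmc: hierfit.MCMCSettings = field(default_factory=hierfit.MCMCSettings)
    seed: int = 0
    window_size: int = preprocess.DEFAULT_WINDOW
    n_vividness_bins: int = 4
    likelihood: str = "gaussian"
    stages: tuple = STAGES
    run_prior_sensitivity: bool = False
    prior_sensitivity_scales: tuple = (0.5, 1.0, 2.0)
    input_trials: str | None = None    # analyse user CSVs instead of simulating
    input_subjects: str | None = None
    output_dir: str = "rivalbias_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            c = dict(d["cohort"])
            if "group_truth" in c and isinstance(c["group_truth"], dict):
                gt = dict(c["group_truth"])
                for key in ("g_beta", "lam_beta", "pi_mixed_beta"):
                    if key in gt:
                        gt[key] = tuple(gt[key])
                c["group_truth"] = simulate.GroupTruth(**gt)
            if isinstance(c.get("profile"), list):
                c["profile"] = tuple(c["profile"])
            d["cohort"] = simulate.CohortConfig(**c)
        if "prior" in d and isinstance(d["prior"], dict):
            p = dict(d["prior"])
            for key in ("g_beta", "lam_beta", "pi_mixed_beta"):
                if key in p:
                    p[key] = tuple(p[key])
            d["prior"] = hierfit.PriorSpec(**p)
        if "mcmc" in d and isinstance(d["mcmc"], dict):
            d["mcmc"] = hierfit.MCMCSettings(**d["mcmc"])
        for key in ("stages", "prior_sensitivity_scales"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh,
                           sort_keys=False)


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers = [logging.StreamHandler(),
                    logging.FileHandler(outdir / "run.log", mode="w")]
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in log.handlers:
        h.setFormatter(fmt)


def run_pipeline(config: RunConfig, output_dir=None) -> Path:
    """Execute the enabled stages; returns the run directory.

    A failing stage aborts the run with the stage named in the raised error;
    outputs of completed stages are retained.
    """
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    config.to_yaml(outdir / "resolved_config.yaml")
    log.info("run started: seed=%s stages=%s", config.seed, list(config.stages))

    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FNS[stage](config, state, outdir)
        except Exception as exc:
            log.error("stage %r failed: %s", stage, exc)
            raise RuntimeError(f"pipeline stage {stage!r} failed") from exc
        log.info("stage %s done in %.1fs", stage, time.perf_counter() - t0)
    log.info("run finished: %s", outdir)
    return outdir


def _stage_simulate(cfg: RunConfig, state: dict, outdir: Path) -> None:
    if cfg.input_trials:
        trials = pd.read_csv(cfg.input_trials)
        subjects = (pd.read_csv(cfg.input_subjects)
                    if cfg.input_subjects else
                    pd.DataFrame({"subject_id": sorted(trials["subject_id"].unique()),
                                  "vviq": np.nan}))
        state["trials"], state["subjects"] = trials, subjects
        log.info("loaded %d trials from %s", len(trials), cfg.input_trials)
        return
    cohort = simulate.simulate_cohort(cfg.cohort, cfg.seed)
    state["trials"], state["subjects"] = cohort.trials, cohort.subjects
    cohort.trials.to_csv(outdir / "trials.csv", index=False)
    cohort.subjects.to_csv(outdir / "subjects.csv", index=False)
    cohort.truth.to_csv(outdir / "ground_truth.csv", index=False)
    log.info("simulated %d subjects, %d trials",
             cohort.trials["subject_id"].nunique(), len(cohort.trials))


def _stage_preprocess(cfg: RunConfig, state: dict, outdir: Path) -> None:
    trials, report = preprocess.apply_exclusions(state["trials"])
    state["trials"] = trials
    with open(outdir / "exclusions.json", "w") as fh:
        json.dump({"excluded": report.excluded,
                   "mock_priming_mean": report.mock_priming_mean,
                   "mock_priming_sd": report.mock_priming_sd,
                   "threshold": report.threshold}, fh, indent=2)
    curves = preprocess.derive_all_curves(trials, cfg.window_size)
    state["curves"] = curves
    pd.concat([c.to_frame() for c in curves], ignore_index=True).to_csv(
        outdir / "dominance_curves.csv", index=False)

    scores = []
    for sid, sub in trials.groupby("subject_id", sort=True):
        scores.append({
            "subject_id": sid,
            "priming": preprocess.priming_proportion(sub),
            "mock_priming": preprocess.mock_priming(sub[sub["is_catch"]]),
        })
    state["subject_scores"] = pd.DataFrame(scores)
    state["subject_scores"].to_csv(outdir / "subject_scores.csv", index=False)
    log.info("excluded %d subjects; %d curves derived",
             len(report.excluded), len(curves))


def _stage_fit(cfg: RunConfig, state: dict, outdir: Path) -> None:
    if cfg.likelihood == "trials":
        rivalry = state["trials"]
        model = hierfit.build_model(None, cfg.prior, likelihood="trials",
                                    trials=rivalry)
    else:
        model = hierfit.build_model(state["curves"], cfg.prior)
    log.info("fitting %s", model.describe())
    settings = dataclasses.replace(cfg.mcmc, seed=cfg.seed)
    draws = hierfit.fit(model, settings)
    state["draws"] = draws
    summary = hierfit.summarize(draws)
    summary.to_csv(outdir / "posterior_summary.csv", index=False)
    np.savez_compressed(outdir / "posterior_draws.npz", **draws.posterior)
    diag = draws.diagnostics
    log.info("fit done, max R-hat %.3f", diag.max_rhat)


def _stage_evidence(cfg: RunConfig, state: dict, outdir: Path) -> None:
    bfs = evidence.compute_bayes_factors(state["draws"], seed=cfg.seed)
    bfs.to_csv(outdir / "bayes_factors.csv", index=False)
    state["bayes_factors"] = bfs
    if cfg.run_prior_sensitivity:
        settings = dataclasses.replace(cfg.mcmc, seed=cfg.seed)
        table = evidence.prior_sensitivity(
            state["curves"], cfg.prior, cfg.prior_sensitivity_scales, settings)
        table.to_csv(outdir / "prior_sensitivity.csv", index=False)
    grp = bfs[bfs["level"] == "group"]
    for _, row in grp.iterrows():
        log.info("group %s: log BF = %.2f (%s)", row["parameter"],
                 row["log_bf"], row["category"])


def _stage_classical(cfg: RunConfig, state: dict, outdir: Path) -> None:
    scores = state["subject_scores"]
    lines, rows = [], []

    t_prime = classical.one_sample_t(scores["priming"], 0.5)
    rows.append({"test": "priming_vs_chance", **t_prime.__dict__})
    lines.append(f"Rivalry priming vs 0.5: M = {t_prime.mean:.3f}, "
                 f"SD = {t_prime.sd:.3f}, t({t_prime.df}) = {t_prime.t:.2f}, "
                 f"p = {t_prime.p:.4f}, d = {t_prime.cohen_d:.2f}")
    t_mock = classical.one_sample_t(scores["mock_priming"], 0.5)
    rows.append({"test": "mock_priming_vs_chance", **t_mock.__dict__})
    lines.append(f"Mock priming vs 0.5: M = {t_mock.mean:.3f}, "
                 f"SD = {t_mock.sd:.3f}, t({t_mock.df}) = {t_mock.t:.2f}, "
                 f"p = {t_mock.p:.4f}")
    corr = classical.pearson_bf(scores["mock_priming"], scores["priming"])
    rows.append({"test": "mock_vs_rivalry_priming", **corr.__dict__})
    lines.append(f"Mock vs rivalry priming: r = {corr.r:.2f}, "
                 f"p = {corr.p:.2f}, BF10 = {corr.bf10:.2f}")

    subjects = state.get("subjects")
    if subjects is not None and subjects["vviq"].notna().all():
        merged = scores.merge(subjects, on="subject_id")
        corr_v = classical.pearson_bf(merged["vviq"], merged["priming"])
        rows.append({"test": "vviq_vs_priming", **corr_v.__dict__})
        lines.append(f"VVIQ vs priming: r = {corr_v.r:.2f}, p = {corr_v.p:.2f}, "
                     f"BF10 = {corr_v.bf10:.2f}")

    table, flagged = classical.vividness_bins(state["trials"], cfg.n_vividness_bins)
    table.to_csv(outdir / "vividness_bins.csv")
    if len(table) >= 3:
        an = classical.rm_anova_hf(table.to_numpy())
        rows.append({"test": "vividness_rm_anova", "F": an.F, "df1": an.df1,
                     "df2": an.df2, "p": an.p, "epsilon_hf": an.epsilon_hf,
                     "F_linear": an.F_linear, "p_linear": an.p_linear})
        lines.append(
            f"Vividness ANOVA ({len(table)} subjects, {len(flagged)} dropped): "
            f"F({an.df1:.2f},{an.df2:.2f}) = {an.F:.2f}, p = {an.p:.3f}, "
            f"Huynh-Feldt eps = {an.epsilon_hf:.3f}; linear contrast "
            f"F(1,{an.df_linear[1]}) = {an.F_linear:.2f}, p = {an.p_linear:.3f}")

    pd.DataFrame(rows).to_csv(outdir / "classical_stats.csv", index=False)
    report = "\n".join(lines) + "\n"
    (outdir / "classical_report.txt").write_text(report)
    for line in lines:
        log.info("%s", line)


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "fit": _stage_fit,
    "evidence": _stage_evidence,
    "classical": _stage_classical,
}

# cumulative prerequisites for each CLI subcommand
_CLI_STAGES = {
    "simulate": ("simulate",),
    "preprocess": ("simulate", "preprocess"),
    "fit": ("simulate", "preprocess", "fit"),
    "evidence": ("simulate", "preprocess", "fit", "evidence"),
    "classical": ("simulate", "preprocess", "classical"),
    "all": STAGES,
    "report": STAGES,
}


@click.group()
def cli():
    """Imagery / binocular-rivalry analysis pipeline."""


def _make_command(name: str):
    @cli.command(name=name, help=f"Run the pipeline through the {name!r} stage.")
    @click.option("--config", "config_path", type=click.Path(exists=True),
                  default=None, help="YAML run configuration.")
    @click.option("--seed", type=int, default=None, help="Master seed override.")
    @click.option("--out", "out_dir", type=click.Path(), default=None,
                  help="Output directory override.")
    @click.option("--subjects", "n_subjects", type=int, default=None,
                  help="Cohort size override.")
    def _cmd(config_path, seed, out_dir, n_subjects):
        config = (RunConfig.from_yaml(config_path) if config_path else RunConfig())
        if seed is not None:
            config.seed = seed
        if out_dir is not None:
            config.output_dir = out_dir
        if n_subjects is not None:
            config.cohort = dataclasses.replace(config.cohort,
                                                n_subjects=n_subjects)
        config.stages = _CLI_STAGES[name]
        run_pipeline(config)

    return _cmd


for _name in _CLI_STAGES:
    _make_command(_name)
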