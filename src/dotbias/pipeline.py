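"""Orchestration: simulate -> trim -> fit -> split -> group statistics.

The full workflow mirrors the blocked 2AFC protocol: a cohort of
synthetic observers each runs 180 trials per (reference numerosity x
condition) cell; per-subject trial logs are trimmed on reaction time and
fit with cumulative Gaussians; per-subject percent biases are split into
a low-numerosity regime (N15-N50, where connecting dots produces a large
underestimation) and a high regime (N100, where it largely vanishes);
and the report correlates the low-regime connected bias with AQ, compares
median-split AQ groups, and runs the within-subject ANOVA and the Weber
fraction comparison, each with classical statistics and Bayes factors.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import GeometryConfig
from .observer import (CohortSpec, SessionPlan, TRIAL_COLUMNS,
                       sample_cohort, simulate_session)
from .psychometrics import fit_psychometric, trim_rt
from .quest import PerturbationConfig, QuestConfig
from . import stats as st

__all__ = [
    "RunConfig",
    "SessionPlan",
    "run_experiment",
    "simulate_cohort_trials",
    "analyze",
    "report",
    "load_config",
    "save_config",
    "FIT_COLUMNS",
]

logger = logging.getLogger("dotbias")

FIT_COLUMNS = ["subject_id", "aq", "condition", "reference_n", "pse", "sigma",
               "jnd", "wf", "bias_pct", "n_trials_used", "converged"]

LOW_REGIME = (15, 25, 50)
HIGH_REGIME = (100,)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one simulated experiment."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    plan: SessionPlan = field(default_factory=SessionPlan)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    quest: QuestConfig = field(default_factory=QuestConfig)
    perturbation: PerturbationConfig = field(default_factory=PerturbationConfig)
    seed: int = 0
    output_dir: str = "dotbias_run"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"]["connector_length_range"] = list(
            self.geometry.connector_length_range)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = {}
    for key, cls in [("cohort", CohortSpec), ("plan", SessionPlan),
                     ("geometry", GeometryConfig), ("quest", QuestConfig),
                     ("perturbation", PerturbationConfig)]:
        if key in raw:
            sub = dict(raw[key])
            for f in ("reference_numerosities", "conditions",
                      "connector_length_range"):
                if f in sub and isinstance(sub[f], list):
                    sub[f] = tuple(sub[f])
            kwargs[key] = cls(**sub)
    for key in ("seed", "output_dir"):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def _subject_rng(seed: int, index: int) -> tuple[np.random.Generator, int]:
    child = int((seed * 100_003 + 7919 * index + 1) % (2 ** 31))
    return np.random.default_rng([seed, index]), child


def simulate_cohort_trials(cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every subject's session in memory.

    Returns ``(trials, aq_table)``; ``trials`` concatenates all subjects'
    logs, ``aq_table`` has one row per subject (subject_id, aq).
    """
    cohort_rng = np.random.default_rng([cfg.seed, 0xC0407])
    observers = sample_cohort(cfg.cohort, cohort_rng)
    frames = []
    for i, obs in enumerate(observers):
        rng, child_seed = _subject_rng(cfg.seed, i)
        sid = f"s{i + 1:02d}"
        frames.append(simulate_session(
            obs, cfg.plan, rng, quest_cfg=cfg.quest,
            pert_cfg=cfg.perturbation, subject_id=sid, rng_seed=child_seed))
    trials = pd.concat(frames, ignore_index=True)
    aq_table = pd.DataFrame({
        "subject_id": [f"s{i + 1:02d}" for i in range(len(observers))],
        "aq": [o.aq for o in observers]})
    return trials, aq_table


def run_experiment(cfg: RunConfig) -> dict:
    """Simulate and write one CSV per subject plus a manifest."""
    t0 = time.perf_counter()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        trials, aq_table = simulate_cohort_trials(cfg)
        for sid, sub in trials.groupby("subject_id", sort=True):
            path = out / f"trials_{sid}.csv"
            sub.to_csv(path, index=False)
            written.append(path)
        aq_path = out / "aq_table.csv"
        aq_table.to_csv(aq_path, index=False)
        written.append(aq_path)
        manifest = {
            "config": cfg.to_dict(),
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "n_subjects": int(aq_table.shape[0]),
            "trials_per_subject": cfg.plan.total_trials,
            "files": [p.name for p in written],
        }
        mpath = out / "manifest.json"
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        written.append(mpath)
    except Exception:
        for p in written:           # no partial outputs on failure
            p.unlink(missing_ok=True)
        raise
    logger.info("simulate: %d subjects x %d trials in %.1fs",
                len(aq_table), cfg.plan.total_trials, time.perf_counter() - t0)
    return manifest


def _validate_schema(trials: pd.DataFrame) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial log is missing columns: {missing}")


def analyze(trials: pd.DataFrame, lapse: float = 0.0) -> pd.DataFrame:
    """Per-subject, per-condition, per-numerosity psychometric fits.

    RT trimming (mean +/- 2 SD per subject over the whole session) is
    applied once before fitting.  Returns the fits table; the fraction of
    trials removed is attached as ``fits.attrs['trim_fraction']``.
    """
    _validate_schema(trials)
    t0 = time.perf_counter()
    kept, removed = trim_rt(trials)
    rows = []
    for (sid, cond, ref), sub in kept.groupby(
            ["subject_id", "condition", "reference_n"], sort=True):
        fit = fit_psychometric(sub, reference_n=ref, lapse=lapse)
        row = dict(subject_id=sid, aq=int(sub["aq"].iloc[0]), condition=cond,
                   reference_n=int(ref))
        row.update(fit.as_row())
        rows.append(row)
    fits = pd.DataFrame(rows, columns=FIT_COLUMNS)
    fits.attrs["trim_fraction"] = len(removed) / len(trials)
    logger.info("analyze: %d fits (%.2f%% trials trimmed) in %.1fs",
                len(fits), 100 * fits.attrs["trim_fraction"],
                time.perf_counter() - t0)
    return fits


def _subject_summary(fits: pd.DataFrame,
                     low_regime=LOW_REGIME, high_regime=HIGH_REGIME) -> pd.DataFrame:
    """One row per subject: regime-mean biases per condition and mean WF."""
    rows = []
    for sid, sub in fits.groupby("subject_id", sort=True):
        def regime_mean(cond, refs):
            sel = sub[(sub.condition == cond) & sub.reference_n.isin(refs)]
            return float(sel.bias_pct.mean()) if len(sel) else np.nan
        rows.append(dict(
            subject_id=sid, aq=int(sub.aq.iloc[0]),
            bias_low_connected=regime_mean("connected", low_regime),
            bias_high_connected=regime_mean("connected", high_regime),
            bias_low_isolated=regime_mean("isolated", low_regime),
            bias_high_isolated=regime_mean("isolated", high_regime),
            wf_mean=float(sub.wf.mean()),
        ))
    return pd.DataFrame(rows)


def _mean_sem(x) -> dict:
    x = np.asarray(x, float)
    x = x[~np.isnan(x)]
    return {"mean": float(x.mean()),
            "sem": float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0,
            "n": int(len(x))}


def _corr_block(x, y) -> dict:
    r, p = st.pearson_r(x, y)
    bf = st.bf_pearson(r, len(x))
    bf_jzs = st.bf_pearson_jzs(r, len(x))
    return {"r": r, "p": p,
            "log10_bf_stretched_beta": bf.log10_bf10,
            "log10_bf_jzs": bf_jzs.log10_bf10}


def _ttest_block(a, b) -> dict:
    t, df, p = st.two_sample_t(a, b)
    bf = st.bf_ttest_jzs(t, len(a), len(b))
    bf_paired = st.bf_ttest_jzs_paired(t, len(a) + len(b) - 1)
    return {"t": t, "df": df, "p": p,
            "log10_bf_two_sample": bf.log10_bf10,
            "log10_bf_paired_equivalent": bf_paired.log10_bf10}


def report(fits: pd.DataFrame, low_regime=LOW_REGIME,
           high_regime=HIGH_REGIME) -> dict:
    """Group statistics over a fits table.

    Median-splits subjects on AQ, then for each numerosity regime reports
    group mean connected biases (+/- SEM), the bias-AQ Pearson
    correlation with Bayes factors, the between-group t test with Bayes
    factors, the within-subject numerosity x condition ANOVA on percent
    bias, the Weber-fraction group comparison, and a Jarque-Bera check of
    AQ normality.
    """
    summary = _subject_summary(fits, low_regime, high_regime)
    if summary[["bias_low_connected", "bias_high_connected"]].isna().any().any():
        raise ValueError("missing cells: every subject needs connected fits "
                         "in both regimes")
    split = st.median_split(summary.aq.to_numpy(),
                            ids=summary.subject_id.to_numpy())
    low_g = summary[summary.subject_id.isin(split.low_ids)]
    high_g = summary[summary.subject_id.isin(split.high_ids)]

    anova = st.rm_anova_2way(fits, dv="bias_pct", subject="subject_id",
                             within=("reference_n", "condition"))

    jb, jb_p = st.jarque_bera(summary.aq.to_numpy())

    out = {
        "n_subjects": int(len(summary)),
        "median_split": {"threshold": split.threshold,
                         "n_low": len(split.low_ids),
                         "n_high": len(split.high_ids)},
        "aq_normality": {"jb": jb, "p": jb_p},
        "group_means": {
            "low_regime_connected": {
                "low_aq": _mean_sem(low_g.bias_low_connected),
                "high_aq": _mean_sem(high_g.bias_low_connected)},
            "high_regime_connected": {
                "low_aq": _mean_sem(low_g.bias_high_connected),
                "high_aq": _mean_sem(high_g.bias_high_connected)},
            "baseline_isolated": {
                "low_regime": _mean_sem(summary.bias_low_isolated),
                "high_regime": _mean_sem(summary.bias_high_isolated)},
        },
        "bias_vs_aq": {
            "low_regime": _corr_block(summary.aq, summary.bias_low_connected),
            "high_regime": _corr_block(summary.aq, summary.bias_high_connected),
        },
        "group_comparison": {
            "low_regime": _ttest_block(low_g.bias_low_connected,
                                       high_g.bias_low_connected),
            "high_regime": _ttest_block(low_g.bias_high_connected,
                                        high_g.bias_high_connected),
        },
        "anova_bias": anova.to_dict(orient="records"),
        "weber": {
            "low_aq": _mean_sem(low_g.wf_mean),
            "high_aq": _mean_sem(high_g.wf_mean),
            "group_comparison": _ttest_block(low_g.wf_mean, high_g.wf_mean),
        },
        "subject_summary": summary.to_dict(orient="records"),
    }
    return out


def render_report_text(rep: dict) -> str:
    """Human-readable digest of a report dict."""
    L = []
    ms = rep["median_split"]
    L.append(f"N = {rep['n_subjects']} subjects; AQ median split at "
             f"{ms['threshold']:.0f} -> {ms['n_low']} low / {ms['n_high']} high")
    jb = rep["aq_normality"]
    L.append(f"AQ normality: JB = {jb['jb']:.2f}, p = {jb['p']:.2f}")
    for regime in ("low_regime", "high_regime"):
        g = rep["group_means"][regime + "_connected"]
        c = rep["bias_vs_aq"][regime]
        t = rep["group_comparison"][regime]
        L.append(f"[{regime}] connected bias: low-AQ {g['low_aq']['mean']:.1f}"
                 f" +/- {g['low_aq']['sem']:.1f}%, high-AQ "
                 f"{g['high_aq']['mean']:.1f} +/- {g['high_aq']['sem']:.1f}%")
        L.append(f"  bias~AQ: r = {c['r']:.2f}, p = {c['p']:.3g}, "
                 f"log10 BF = {c['log10_bf_jzs']:.2f} (jzs) / "
                 f"{c['log10_bf_stretched_beta']:.2f} (stretched beta)")
        L.append(f"  groups: t({t['df']}) = {t['t']:.2f}, p = {t['p']:.3g}, "
                 f"log10 BF = {t['log10_bf_paired_equivalent']:.2f} (paired-eq)"
                 f" / {t['log10_bf_two_sample']:.2f} (two-sample)")
    for row in rep["anova_bias"]:
        L.append(f"ANOVA {row['effect']}: F({row['df1']},{row['df2']}) = "
                 f"{row['F']:.2f}, p = {row['p']:.3g}")
    w = rep["weber"]
    L.append(f"WF: low-AQ {w['low_aq']['mean']:.3f}, high-AQ "
             f"{w['high_aq']['mean']:.3f}; t = "
             f"{w['group_comparison']['t']:.2f}, log10 BF = "
             f"{w['group_comparison']['log10_bf_two_sample']:.2f}")
    return "\n".join(L)
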