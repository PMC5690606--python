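"""Study orchestration: simulate -> preprocess -> GLM/SNR -> MVPA -> trajectory.

`analyze_session` and `analyze_study` are the in-memory workhorses;
`run_study` wires them to a simulated longitudinal study and writes all
stage outputs (CSV/JSON) plus a reproducibility manifest. Identical
config and seed produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .contrasts import STANDARD_CONTRASTS, ContrastDef
from .devtraj import (
    NakaRushtonFit,
    bootstrap_criterion_ages,
    compare_crossing_ages,
    criterion_age,
    dprime,
    fit_naka_rushton,
)
from .glmmap import (
    build_contrast_design,
    build_design,
    fit_glm,
    onset_regression,
    percent_significant,
    threshold,
)
from .mvpa import (
    ClassificationResult,
    ContrastNotApplicableError,
    assemble_patterns,
    chance_level,
    crossvalidate,
    rank_voxels,
)
from .preprocess import detrend_run
from .snrspec import SnrSpec, spectral_snr
from .synthbold import (
    BoldRun,
    GroundTruthDevelopment,
    SessionConfig,
    default_ground_truth,
    make_longitudinal_study,
)

logger = logging.getLogger("glassdev")

__all__ = ["StudyConfig", "SessionAnalysis", "StudyResult", "analyze_session", "analyze_study", "run_study"]


@dataclass
class StudyConfig:
    """Simulation spec plus analysis thresholds for one reproducible study."""

    ages: Sequence[float] = (3.4, 6.0, 9.0, 12.0, 18.0, 24.0, 36.0, 48.0)
    voi_labels: Sequence[str] = ("V1", "V4", "MT-V5")
    n_voxels_per_voi: int = 100
    noise_sd: float = 8.0
    a_half: Mapping[str, float] | None = None
    dmax: float = 6.0
    nr_shape: float = 2.0
    amp_scale: float = 0.5
    weight_scale: float = 0.25
    contrasts: Sequence[str] = tuple(STANDARD_CONTRASTS)
    truncation: int = 70
    fdr_q: float = 0.05
    bonferroni_alpha: float = 0.05
    criterion: float = 2.0
    n_bootstrap: int = 1000
    zscore: bool = True
    seed: int = 0
    out_dir: str = "glassdev_output"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ages"] = list(self.ages)
        d["voi_labels"] = list(self.voi_labels)
        d["contrasts"] = list(self.contrasts)
        if self.a_half is not None:
            d["a_half"] = dict(self.a_half)
        return d


@dataclass
class SessionAnalysis:
    """All per-session stage outputs for one scanning session."""

    age: float
    qc_p95: float
    snr: dict[str, float]
    glm_percent: dict[tuple[str, str], tuple[float, bool]]
    mvpa: dict[tuple[str, str], ClassificationResult]
    dropped: dict[tuple[str, str], str]
    sensitivity: dict[tuple[str, str], object]


def analyze_session(
    pinwheel_run: BoldRun,
    glass_runs: list[BoldRun],
    age: float,
    contrasts: Mapping[str, ContrastDef] | None = None,
    truncation: int = 70,
    bonferroni_alpha: float = 0.05,
    zscore: bool = True,
    cv_seed: int = 0,
    detrend: bool = True,
) -> SessionAnalysis:
    """Run preprocessing, signal quality, GLM summaries and MVPA for one session."""
    contrasts = dict(contrasts or STANDARD_CONTRASTS)
    vois = list(dict.fromkeys(pinwheel_run.voi_of_voxel))

    if detrend:
        pinwheel_run, qc = detrend_run(pinwheel_run)
        qc_p95 = qc.p95
        glass_runs = [detrend_run(r)[0] for r in glass_runs]
    else:
        qc_p95 = float("nan")

    snr_spec = SnrSpec(tr=pinwheel_run.tr)
    snr = {v: spectral_snr(pinwheel_run.voi_mean_series(v), snr_spec) for v in vois}

    pin_design = build_design(pinwheel_run.schedule, pinwheel_run.tr)
    pin_glm = fit_glm(pinwheel_run, pin_design)

    glm_percent: dict[tuple[str, str], tuple[float, bool]] = {}
    mvpa_results: dict[tuple[str, str], ClassificationResult] = {}
    dropped: dict[tuple[str, str], str] = {}
    sensitivity: dict[tuple[str, str], object] = {}

    rankings = {
        v: rank_voxels(pin_glm, pinwheel_run.voi_indices(v), voi=v, truncation=truncation)
        for v in vois
    }

    schedule = glass_runs[0].schedule
    for cname, cdef in contrasts.items():
        try:
            design = build_contrast_design(schedule, glass_runs[0].tr, cdef)
        except ValueError as exc:
            for v in vois:
                dropped[(v, cname)] = str(exc)
            continue
        glm = fit_glm(glass_runs[0], design)
        for v in vois:
            idx = pinwheel_run.voi_indices(v)
            mask = threshold(glm, "bonferroni_within_voi", bonferroni_alpha, voi_indices=idx)
            pct = percent_significant(mask, idx)
            glm_percent[(v, cname)] = (pct, pct > 0.0)

            ranking = rankings[v]
            if ranking.empty:
                dropped[(v, cname)] = "no positively responsive voxels"
                continue
            try:
                patterns = assemble_patterns(glass_runs, cdef, ranking)
                result = crossvalidate(
                    patterns,
                    pool_size=min(truncation, len(ranking)),
                    zscore=zscore,
                    seed=cv_seed,
                )
            except (ContrastNotApplicableError, ValueError) as exc:
                logger.warning("session age %.1f, %s/%s dropped: %s", age, v, cname, exc)
                dropped[(v, cname)] = str(exc)
                continue
            mvpa_results[(v, cname)] = result
            sensitivity[(v, cname)] = dprime(
                result.mean_accuracy,
                result.sd_accuracy,
                result.n_patterns,
                below_chance=result.below_chance,
            )
    return SessionAnalysis(
        age=age,
        qc_p95=qc_p95,
        snr=snr,
        glm_percent=glm_percent,
        mvpa=mvpa_results,
        dropped=dropped,
        sensitivity=sensitivity,
    )


@dataclass
class StudyResult:
    """Study-level tables and trajectory fits assembled from session analyses."""

    sessions: list[SessionAnalysis]
    fits: dict[tuple[str, str], NakaRushtonFit]
    criterion_ages: dict[tuple[str, str], float | None]
    bootstrap_ages: dict[tuple[str, str], np.ndarray]
    comparisons: pd.DataFrame
    onset: pd.DataFrame

    def mvpa_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.sessions):
            for (voi, cname), res in s.mvpa.items():
                si = s.sensitivity[(voi, cname)]
                rows.append(
                    {
                        "session": i,
                        "age_months": s.age,
                        "voi": voi,
                        "contrast": cname,
                        "fold_accuracies": json.dumps(list(res.fold_accuracies)),
                        "mean_accuracy": res.mean_accuracy,
                        "sd_accuracy": res.sd_accuracy,
                        "n_patterns": res.n_patterns,
                        "chance_upper": res.chance.upper,
                        "chance_lower": res.chance.lower,
                        "below_chance": res.below_chance,
                        "dprime": si.dprime,
                        "significant": si.significant,
                    }
                )
        return pd.DataFrame(rows)

    def glm_frame(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.sessions):
            for (voi, cname), (pct, sig) in s.glm_percent.items():
                rows.append(
                    {
                        "session": i,
                        "age_months": s.age,
                        "voi": voi,
                        "contrast": cname,
                        "percent_significant": pct,
                        "significant": sig,
                    }
                )
        return pd.DataFrame(rows)

    def trajectory_dict(self) -> dict:
        out = {}
        for key, fit in self.fits.items():
            voi, cname = key
            ages = self.bootstrap_ages.get(key)
            ci = None
            if ages is not None and ages.size:
                finite = np.isfinite(ages)
                if finite.mean() >= 0.975:
                    lo, hi = np.percentile(ages[finite], [2.5, 97.5])
                    ci = [float(lo), float(hi)]
            crit = self.criterion_ages[key]
            out[f"{voi}|{cname}"] = {
                "dmax": fit.dmax,
                "a_half": fit.a_half,
                "shape": fit.shape,
                "rss": fit.rss,
                "criterion_age_months": crit,
                "criterion_reached": crit is not None,
                "criterion_age_ci95": ci,
            }
        return out


def analyze_study(
    analyses: list[SessionAnalysis],
    contrasts: Sequence[str],
    voi_labels: Sequence[str],
    criterion: float = 2.0,
    n_bootstrap: int = 1000,
    seed: int = 0,
    max_age_horizon: float | None = None,
) -> StudyResult:
    """Fit developmental trajectories and pairwise comparisons across sessions.

    A fitted curve that only crosses the criterion beyond
    ``max_age_horizon`` (default: the oldest analyzed session) is an
    extrapolation outside the studied range and is reported not-reached.
    """
    analyses = sorted(analyses, key=lambda s: s.age)
    if max_age_horizon is None and analyses:
        max_age_horizon = max(s.age for s in analyses)
    fits: dict[tuple[str, str], NakaRushtonFit] = {}
    crit_ages: dict[tuple[str, str], float | None] = {}
    boot: dict[tuple[str, str], np.ndarray] = {}
    ss = np.random.SeedSequence(seed)
    subseeds = iter(ss.generate_state(len(voi_labels) * len(contrasts) * 2))

    for voi in voi_labels:
        for cname in contrasts:
            key = (voi, cname)
            triples = [
                (
                    s.age,
                    list(s.mvpa[key].fold_accuracies),
                    s.mvpa[key].n_patterns,
                )
                for s in analyses
                if key in s.mvpa
            ]
            sub = int(next(subseeds))
            if len(triples) < 4:
                logger.warning("%s/%s: only %d sessions, skipping fit", voi, cname, len(triples))
                continue
            ages = [t[0] for t in triples]
            dvals = [s.sensitivity[key].dprime for s in analyses if key in s.sensitivity]
            fit = fit_naka_rushton(ages, dvals)
            fits[key] = fit
            crit = criterion_age(fit, criterion)
            if crit is not None and max_age_horizon is not None and crit > max_age_horizon:
                crit = None
            crit_ages[key] = crit
            if n_bootstrap > 0:
                boot[key] = bootstrap_criterion_ages(
                    triples, B=n_bootstrap, seed=sub, criterion=criterion
                )

    comp_rows = []
    for cname in contrasts:
        for voi_a in voi_labels:
            for voi_b in voi_labels:
                if voi_a == voi_b:
                    continue
                ka, kb = (voi_a, cname), (voi_b, cname)
                if ka in boot and kb in boot:
                    comp_rows.append(
                        {
                            "contrast": cname,
                            "voi_older": voi_a,
                            "voi_younger": voi_b,
                            "p": compare_crossing_ages(boot[ka], boot[kb]),
                        }
                    )
    comparisons = pd.DataFrame(comp_rows)

    onset_rows = []
    for voi in voi_labels:
        for cname in contrasts:
            pts = [
                (s.age, *s.glm_percent[(voi, cname)])
                for s in analyses
                if (voi, cname) in s.glm_percent
            ]
            if not pts:
                continue
            reg = onset_regression(pts)
            onset_rows.append(
                {
                    "voi": voi,
                    "contrast": cname,
                    "qualified": reg.qualified,
                    "slope": reg.slope,
                    "intercept": reg.intercept,
                    "r_squared": reg.r_squared,
                    "onset_age_months": reg.onset_age,
                    "reason": reg.reason,
                }
            )
    onset = pd.DataFrame(onset_rows)
    return StudyResult(
        sessions=analyses,
        fits=fits,
        criterion_ages=crit_ages,
        bootstrap_ages=boot,
        comparisons=comparisons,
        onset=onset,
    )


def run_study(config: StudyConfig, write: bool = True) -> StudyResult:
    """Simulate a longitudinal study, analyze every stage, write outputs."""
    truth = default_ground_truth(
        a_half=dict(config.a_half) if config.a_half else None,
        dmax=config.dmax,
        shape=config.nr_shape,
        amp_scale=config.amp_scale,
        weight_scale=config.weight_scale,
    )
    template = SessionConfig(
        age=0.0,
        n_voxels={v: config.n_voxels_per_voi for v in config.voi_labels},
        noise_sd=config.noise_sd,
    )
    sessions = make_longitudinal_study(config.ages, template, truth, seed=config.seed)
    contrasts = {name: STANDARD_CONTRASTS[name] for name in config.contrasts}
    cv_seeds = np.random.SeedSequence(config.seed).generate_state(len(sessions) + 1)

    analyses = []
    for i, session in enumerate(sessions):
        try:
            analyses.append(
                analyze_session(
                    session.pinwheel_run,
                    session.glass_runs,
                    session.age,
                    contrasts=contrasts,
                    truncation=config.truncation,
                    bonferroni_alpha=config.bonferroni_alpha,
                    zscore=config.zscore,
                    cv_seed=int(cv_seeds[i]),
                )
            )
            logger.info("session %d (age %.1f mo) analyzed", i, session.age)
        except Exception as exc:  # noqa: BLE001 - study continues on session failure
            logger.error("session %d (age %.1f mo) failed: %s", i, session.age, exc)
    result = analyze_study(
        analyses,
        contrasts=list(config.contrasts),
        voi_labels=list(config.voi_labels),
        criterion=config.criterion,
        n_bootstrap=config.n_bootstrap,
        seed=config.seed,
    )
    if write:
        _write_outputs(config, result)
    return result


def _write_outputs(config: StudyConfig, result: StudyResult) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.mvpa_frame().to_csv(out / "mvpa_sessions.csv", index=False)
    result.glm_frame().to_csv(out / "glm_percent.csv", index=False)
    result.onset.to_csv(out / "onset_regression.csv", index=False)
    result.comparisons.to_csv(out / "comparisons.csv", index=False)
    qc = pd.DataFrame(
        {
            "session": range(len(result.sessions)),
            "age_months": [s.age for s in result.sessions],
            "qc_p95_percent": [s.qc_p95 for s in result.sessions],
        }
    )
    qc.to_csv(out / "qc.csv", index=False)
    snr_rows = [
        {"session": i, "age_months": s.age, "voi": v, "snr": snr}
        for i, s in enumerate(result.sessions)
        for v, snr in s.snr.items()
    ]
    pd.DataFrame(snr_rows).to_csv(out / "snr.csv", index=False)
    with open(out / "trajectory.json", "w") as fh:
        json.dump(result.trajectory_dict(), fh, indent=2, sort_keys=True)
    cfg = config.to_dict()
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
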