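"""End-to-end pipeline: simulate -> classify -> summarize -> analyze.

Given a cohort specification, the pipeline simulates (or loads) sessions,
classifies localisation responses into target/misbinding/guessing, builds
tidy per-participant-per-condition summaries, and runs the inferential
layer: within-subject ANOVAs on each memory measure, mixed group ANOVAs with
Holm-corrected pairwise contrasts when several groups are present,
VVIQ correlations with the memory measures and with age/TIV-residualized
regional volumes, and group t-tests on the covariates.

Every stage is deterministic given the master seed, and ``run_pipeline``
writes its artifacts (CSV/JSON) with provenance metadata.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import metrics as _metrics
from . import stats as _stats
from .synthio import (
    CohortSpec,
    ParticipantRecord,
    clinical_cohort_spec,
    healthy_cohort_spec,
    simulate_cohort,
)
from .taskio import write_sessions

__all__ = [
    "PipelineConfig",
    "MEMORY_MEASURES",
    "classify_cohort",
    "participant_measure_means",
    "covariates_frame",
    "analyze_cohort",
    "run_pipeline",
    "config_from_yaml",
]

logger = logging.getLogger("whatwhere")

#: analysis measure name -> summary-table column
MEMORY_MEASURES = {
    "identification_accuracy": "identification_accuracy",
    "localisation_error": "mean_localisation_error_px",
    "reaction_time": "mean_rt_s",
    "misbinding": "mean_p_misbind",
    "guessing": "mean_p_guess",
}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one reproducible run needs."""

    cohort: CohortSpec
    seed: int = 0
    n_resamples: int = _classify.DEFAULT_N_RESAMPLES
    include_incorrect: bool = False
    exact: bool = False
    alpha: float = 0.05
    posthoc: str = "holm"
    welch: bool = False
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.posthoc not in ("holm", "none"):
            raise ValueError("posthoc must be 'holm' or 'none'")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")


def config_from_yaml(path: Union[str, Path]) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    The ``cohort`` section selects a preset (``healthy`` or ``clinical``)
    with its keyword arguments, e.g.::

        seed: 7
        cohort: {preset: clinical, n_per_group: 19, n_per_condition: 30}
        classifier: {n_resamples: 5000, include_incorrect: false, exact: false}
        analysis: {alpha: 0.05, posthoc: holm, welch: false}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    seed = int(raw.get("seed", 0))
    cohort_cfg = dict(raw.get("cohort", {}))
    preset = cohort_cfg.pop("preset", "clinical")
    cohort_cfg.setdefault("seed", seed)
    if preset == "healthy":
        cohort = healthy_cohort_spec(**cohort_cfg)
    elif preset == "clinical":
        cohort = clinical_cohort_spec(**cohort_cfg)
    else:
        raise ValueError(f"unknown cohort preset {preset!r}")
    cls = dict(raw.get("classifier", {}))
    ana = dict(raw.get("analysis", {}))
    return PipelineConfig(
        cohort=cohort,
        seed=seed,
        n_resamples=int(cls.get("n_resamples", _classify.DEFAULT_N_RESAMPLES)),
        include_incorrect=bool(cls.get("include_incorrect", False)),
        exact=bool(cls.get("exact", False)),
        alpha=float(ana.get("alpha", 0.05)),
        posthoc=str(ana.get("posthoc", "holm")),
        welch=bool(ana.get("welch", False)),
        outdir=raw.get("outdir"),
    )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def classify_cohort(
    records: Sequence[ParticipantRecord],
    n_resamples: int = _classify.DEFAULT_N_RESAMPLES,
    seed: Optional[int] = None,
    include_incorrect: bool = False,
    exact: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every participant's session; concatenated tidy tables."""
    per_trial, per_cond = [], []
    for rec in records:
        pt, pc = _classify.classify_session(
            rec,
            n_resamples=n_resamples,
            seed=seed,
            include_incorrect=include_incorrect,
            exact=exact,
        )
        per_trial.append(pt)
        per_cond.append(pc)
    trial_df = pd.concat(per_trial, ignore_index=True)
    cond_df = pd.concat(per_cond, ignore_index=True)
    logger.info(
        "classified %d trials from %d participants (%s mode)",
        len(trial_df), len(records), "exact" if exact else f"{n_resamples} resamples",
    )
    return trial_df, cond_df


def participant_measure_means(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-participant means of each memory measure across conditions."""
    cols = list(MEMORY_MEASURES.values())
    return summary.groupby("participant_id", sort=False)[cols].mean().reset_index()


def covariates_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Tidy covariate table: one row per participant."""
    rows = []
    for rec in records:
        row: dict = {
            "participant_id": rec.participant_id,
            "group": rec.group,
            "age": rec.age,
            "vviq_total": rec.vviq_total,
            "ace": rec.ace,
            "tiv": rec.tiv,
        }
        if rec.volumes:
            for region, v in rec.volumes.items():
                row[f"vol_{region}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def _volume_columns(cov: pd.DataFrame) -> list[str]:
    return [c for c in cov.columns if c.startswith("vol_")]


def _residualized_volumes(cov: pd.DataFrame) -> pd.DataFrame:
    """Volumes corrected for age and TIV (grand mean added back)."""
    out = cov[["participant_id"]].copy()
    has_tiv = "tiv" in cov.columns and cov["tiv"].notna().all()
    for col in _volume_columns(cov):
        v = cov[col].to_numpy(dtype=float)
        if np.isnan(v).any():
            continue
        tiv = cov["tiv"].to_numpy(dtype=float) if has_tiv else np.ones_like(v)
        res = _stats.residualize_volume(v, cov["age"].to_numpy(dtype=float), tiv,
                                        region=col[4:])
        out[col] = res.corrected
    return out


def analyze_cohort(
    summary: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    posthoc: str = "holm",
    welch: bool = False,
    residualize: bool = True,
) -> dict[str, pd.DataFrame]:
    """Run the full inferential layer on a summarised cohort.

    Returns tidy tables: ``anova`` (within-subject effects per measure, or
    mixed-design effects including group when more than one group is
    present), ``posthoc`` (Holm-corrected pairwise group contrasts per
    measure), ``covariate_ttests`` (group contrasts on VVIQ, ACE and
    volumes), and ``correlations`` (VVIQ against memory measures, age, ACE
    and residualized volumes).
    """
    data = summary.merge(
        covariates[["participant_id", "group"]], on="participant_id", how="left"
    )
    groups = sorted(covariates["group"].dropna().unique())
    multi = len(groups) > 1

    anova_rows = []
    for measure, col in MEMORY_MEASURES.items():
        sub = data.dropna(subset=[col])
        try:
            if multi:
                effs = _stats.mixed_anova(sub, col)
            else:
                effs = _stats.rm_anova_2x2(sub, col)
        except ValueError as exc:
            logger.warning("ANOVA skipped for %s: %s", measure, exc)
            continue
        tab = _stats.anova_table(effs)
        tab.insert(0, "measure", measure)
        anova_rows.append(tab)
    anova = pd.concat(anova_rows, ignore_index=True) if anova_rows else pd.DataFrame()

    means = participant_measure_means(summary).merge(
        covariates[["participant_id", "group"]], on="participant_id"
    )

    posthoc_rows: list[dict] = []
    if multi and posthoc == "holm":
        for measure, col in MEMORY_MEASURES.items():
            by_group = {
                g: means.loc[means["group"] == g, col].dropna().to_numpy()
                for g in groups
            }
            for res in _stats.pairwise_group_ttests(by_group, measure=measure,
                                                    welch=welch):
                posthoc_rows.append(
                    {"measure": measure, "comparison": res.comparison,
                     "t": res.t, "df": res.df, "p_raw": res.p_raw,
                     "p_holm": res.p_holm}
                )
    posthoc_df = pd.DataFrame(posthoc_rows)

    cov_t_rows: list[dict] = []
    if multi:
        cov_measures = ["vviq_total"] + (
            ["ace"] if covariates["ace"].notna().all() else []
        ) + _volume_columns(covariates)
        for col in cov_measures:
            if covariates[col].isna().any():
                continue
            for g in groups:
                if g == "control" or "control" not in groups:
                    continue
                res = _stats.independent_ttest(
                    covariates.loc[covariates["group"] == g, col],
                    covariates.loc[covariates["group"] == "control", col],
                    comparison=f"{col}: {g} vs control", welch=welch,
                )
                cov_t_rows.append(
                    {"measure": col, "comparison": res.comparison, "t": res.t,
                     "df": res.df, "p_raw": res.p_raw, "p_holm": None}
                )
    cov_ttests = pd.DataFrame(cov_t_rows)

    corr_rows: list[dict] = []
    cov_m = covariates.merge(means, on="participant_id", suffixes=("", "_m"))
    vviq = cov_m["vviq_total"].to_numpy(dtype=float)
    targets: list[tuple[str, np.ndarray]] = [
        (m, cov_m[col].to_numpy(dtype=float)) for m, col in MEMORY_MEASURES.items()
    ]
    targets.append(("age", cov_m["age"].to_numpy(dtype=float)))
    if cov_m["ace"].notna().all():
        targets.append(("ace", cov_m["ace"].to_numpy(dtype=float)))
    vol_source = _residualized_volumes(covariates) if residualize else covariates
    vol_m = cov_m[["participant_id"]].merge(vol_source, on="participant_id")
    for col in _volume_columns(vol_m):
        targets.append((col, vol_m[col].to_numpy(dtype=float)))
    for name, vals in targets:
        ok = np.isfinite(vals)
        if ok.sum() < 3:
            continue
        try:
            res = _stats.pearson_corr(vviq[ok], vals[ok], pair=f"vviq ~ {name}")
        except ValueError as exc:
            logger.warning("correlation skipped for %s: %s", name, exc)
            continue
        corr_rows.append(
            {"pair": res.pair, "r": res.r, "df": res.df, "n": res.n, "p": res.p}
        )
    correlations = pd.DataFrame(corr_rows)

    return {
        "anova": anova,
        "posthoc": posthoc_df,
        "covariate_ttests": cov_ttests,
        "correlations": correlations,
    }


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _config_digest(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _text_report(results: dict[str, pd.DataFrame], config: PipelineConfig) -> str:
    lines = ["What-was-where pipeline report", "=" * 32, ""]
    lines.append(f"seed: {config.seed}; classifier: "
                 f"{'exact enumeration' if config.exact else f'{config.n_resamples} resamples'}; "
                 f"alpha: {config.alpha}")
    lines.append("")
    for name, df in results.items():
        lines.append(name)
        lines.append("-" * len(name))
        lines.append(df.to_string(index=False) if len(df) else "(empty)")
        lines.append("")
    return "\n".join(lines)


def run_pipeline(
    config: PipelineConfig,
    records: Optional[Sequence[ParticipantRecord]] = None,
) -> dict:
    """Run simulate -> classify -> summarize -> analyze.

    ``records`` may be supplied to analyse pre-loaded (e.g. deposited) data;
    otherwise the cohort is simulated from ``config.cohort`` with
    ``config.seed``.  When ``config.outdir`` is set, all stage artifacts and
    a run-metadata JSON (config hash, seed, package version) are written
    there.
    """
    from . import __version__

    cohort_spec = replace(config.cohort, seed=config.seed)
    if records is None:
        logger.info("simulating cohort (seed=%d)", config.seed)
        records = simulate_cohort(cohort_spec)
    logger.info("cohort: %d participants, %d trials",
                len(records), sum(len(r.trials) for r in records))

    trial_df, cond_df = classify_cohort(
        records,
        n_resamples=config.n_resamples,
        seed=config.seed,
        include_incorrect=config.include_incorrect,
        exact=config.exact,
    )
    summary = _metrics.summarize_cohort(records, cond_df)
    covariates = covariates_frame(records)
    results = analyze_cohort(
        summary, covariates,
        alpha=config.alpha, posthoc=config.posthoc, welch=config.welch,
    )

    out = {
        "records": records,
        "classified_trials": trial_df,
        "classified_conditions": cond_df,
        "summary": summary,
        "covariates": covariates,
        **results,
    }

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sessions(records, outdir / "trials.csv",
                       outdir / "covariates.json")
        trial_df.to_csv(outdir / "classified.csv", index=False)
        summary.to_csv(outdir / "summary.csv", index=False)
        for name in ("anova", "posthoc", "covariate_ttests", "correlations"):
            results[name].to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "report.txt").write_text(_text_report(results, config))
        meta = {
            "config_sha256": _config_digest(config),
            "seed": config.seed,
            "package_version": __version__,
            "n_participants": len(records),
            "n_trials": int(sum(len(r.trials) for r in records)),
            "classifier": "exact" if config.exact else "monte-carlo",
            "n_resamples": config.n_resamples,
            "include_incorrect": config.include_incorrect,
        }
        with open(outdir / "run_metadata.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")
        logger.info("artifacts written to %s", outdir)
    return out
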