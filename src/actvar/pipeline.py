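"""End-to-end orchestration of the activity-variability analysis.

A single config drives: cohort generation (or file ingestion) →
preprocessing (sleep labels, MET floor, missingness exclusion) → gap-fill
evaluation and filling → daily summaries → variability metrics → the named
group comparisons → weekend-rhythm clustering → the factor GAM.  Every
stage's output is serialized under the output directory and a manifest
records the config hash, seed and package versions so a rerun with the
same config reproduces all deterministic outputs.

The analysis recipes carry their Bonferroni denominators explicitly (they
are part of the protocol, not inferred): 3 comparisons for the per-state
metric families, 3 for sex-by-cyclic cells, 15 for age-bin pairs, 6 for
sex-within-age and sex-by-rhythm cells.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .gam import select_model
from .imputation import GAP_GRID, FillPolicy, evaluate_fillers, fill_series
from .inference import compare_groups, subpopulation_effect
from .metrics import variability_profile
from .preprocess import exclude_by_missingness, apply_met_floor
from .rhythms import assign_weekend_rhythm, rhythm_group_stats, select_window
from .summaries import summarize_cohort
from .synthetic import CohortSpec, generate_cohort

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run."""

    mode: str = "synthetic"            # "synthetic" | "files"
    outdir: str = "actvar_out"
    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    input_dir: str | None = None       # files mode: directory from write_cohort
    met_floor: float = 0.9
    missingness_threshold_pct: float = 29.0
    gap_grid: tuple = GAP_GRID
    run_fill_evaluation: bool = True
    policy_override: dict | None = None
    n_clusters: int = 5
    weekend_contrast_threshold: float = 0.25
    recipes: tuple = ("by_sex", "by_cyclic", "by_age", "by_sex_within_age",
                      "by_rhythm", "subpopulations")

    def config_hash(self) -> str:
        def canon(obj):
            if isinstance(obj, dict):
                return sorted((str(k), canon(v)) for k, v in obj.items())
            if isinstance(obj, (list, tuple)):
                return [canon(v) for v in obj]
            return str(obj)

        fields = asdict(self)
        fields.pop("outdir", None)  # where outputs land doesn't change them
        payload = json.dumps(canon(fields))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_files_cohort(config: PipelineConfig):
    from .preprocess import ingest, read_sleep_summary, label_sleep

    root = Path(config.input_dir)
    meta = pd.read_csv(root / "metadata.csv")
    summaries = read_sleep_summary(root / "sleep_summary.csv")
    series = []
    for pid in meta["participant_id"]:
        for ext in ("csv", "parquet"):
            path = root / "participants" / f"{pid}.{ext}"
            if path.exists():
                break
        else:
            raise FileNotFoundError(f"no minute file for {pid}")
        ats = ingest(path, pid)
        if pid in summaries:
            ats = label_sleep(ats, summaries[pid])
        series.append(ats)
    return series, meta


def run(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the in-memory report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    def stage(name):
        log.info("stage: %s", name)

    try:
        stage("input")
        if config.mode == "synthetic":
            config.cohort.seed = config.seed
            series, meta, ground_truth = generate_cohort(config.cohort)
            ground_truth.drop(columns=[], errors="ignore").to_csv(
                outdir / "ground_truth.csv", index=False)
        elif config.mode == "files":
            series, meta = _load_files_cohort(config)
            ground_truth = None
        else:
            raise ValueError(f"unknown mode {config.mode!r}")
        meta.to_csv(outdir / "metadata.csv", index=False)

        stage("preprocess")
        series = [apply_met_floor(s, config.met_floor) for s in series]
        series, excluded = exclude_by_missingness(
            series, config.missingness_threshold_pct)
        report["n_kept"] = len(series)
        report["n_excluded"] = len(excluded)

        stage("fill")
        if config.policy_override:
            policy = FillPolicy(dict(config.policy_override))
        elif config.run_fill_evaluation and any(s.missing_mask.any() for s in series):
            evaluation, policy = evaluate_fillers(
                series, config.gap_grid, seed=config.seed)
            evaluation.table.to_csv(outdir / "fill_evaluation.csv", index=False)
            report["fill_policy"] = dict(policy.methods)
        else:
            policy = FillPolicy.from_breakpoint()
        filled = [fill_series(s, policy) for s in series]

        stage("summaries")
        daily = summarize_cohort(filled)
        daily.to_csv(outdir / "daily_summaries.csv", index=False)

        stage("metrics")
        profile = variability_profile(daily)
        profile.to_csv(outdir / "variability_metrics.csv", index=False)
        report["metrics"] = profile

        stage("rhythms")
        window = select_window(daily["date"], allow_shorter=True)
        labels = assign_weekend_rhythm(daily, config.n_clusters,
                                       config.weekend_contrast_threshold,
                                       window)
        labels.to_csv(outdir / "cluster_assignments.csv", index=False)
        report["rhythm_labels"] = labels

        stage("inference")
        comparisons = _run_recipes(config, profile, daily, labels, meta, window)
        report["comparisons"] = comparisons
        _write_comparisons(comparisons, outdir / "comparisons.json")

        stage("gam")
        gam_table = build_gam_table(profile, labels, meta)
        selection = select_model(gam_table)
        report["gam"] = selection
        _write_gam(selection, gam_table, outdir / "gam_report.json")

        stage("manifest")
        manifest = {
            "actvar_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        report["manifest"] = manifest
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline aborted: {exc}") from exc
    return report


def build_gam_table(profile: pd.DataFrame, labels: pd.DataFrame,
                    meta: pd.DataFrame) -> pd.DataFrame:
    """Per-participant factor table (cdi, sex, wr, age, cyclic) for the GAM."""
    cdi24 = profile[profile["state"] == "24h"].set_index("participant_id")["cdi"]
    table = meta.set_index("participant_id").join(cdi24.rename("cdi"))
    table = table.join(labels.set_index("participant_id")["rhythm_label"])
    table["wr"] = np.where(table["rhythm_label"] == "patternless",
                           "patternless", "weekend_rhythm")
    table["age"] = table["age_bin"]
    table["cyclic"] = np.where(table["cyclic"].astype(bool), "cyclic", "acyclic")
    return table.reset_index()[["participant_id", "cdi", "sex", "wr", "age", "cyclic"]]


def _safe_compare(out, name, values, labels, n_comparisons):
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2 or (counts < 2).any():
        log.warning("recipe %s skipped: a group has fewer than 2 members", name)
        return
    out[name] = compare_groups(values, labels, n_comparisons=n_comparisons)


def _run_recipes(config, profile, daily, labels, meta, window=None) -> dict:
    out = {}
    merged = (profile[profile["state"] == "24h"]
              .merge(meta, on="participant_id")
              .merge(labels, on="participant_id"))
    if "by_sex" in config.recipes:
        # one of the 3 per-state CDI comparisons (Bonferroni /3)
        _safe_compare(out, "cdi_by_sex", merged["cdi"], merged["sex"], 3)
    if "by_cyclic" in config.recipes and merged["cyclic"].nunique() == 2:
        cells = np.where(merged["cyclic"].astype(bool), "cyclic_female",
                         np.where(merged["sex"] == "male",
                                  "acyclic_male", "acyclic_female"))
        if len(np.unique(cells)) == 3:
            _safe_compare(out, "cdi_by_sex_cyclic", merged["cdi"], cells, 3)
    if "by_age" in config.recipes and merged["age_bin"].nunique() > 1:
        _safe_compare(out, "cdi_by_age", merged["cdi"], merged["age_bin"], 15)
    if "by_sex_within_age" in config.recipes:
        for age_bin, g in merged.groupby("age_bin"):
            if g["sex"].nunique() == 2:
                _safe_compare(out, f"cdi_by_sex_age_{age_bin}",
                              g["cdi"], g["sex"], 6)
    if "by_rhythm" in config.recipes:
        out.update(rhythm_group_stats(daily, labels, meta, window))
    if "subpopulations" in config.recipes and merged["cyclic"].any():
        cyc_ids = meta.loc[meta["cyclic"].astype(bool), "participant_id"]
        female_daily = daily[daily["participant_id"].isin(
            meta.loc[meta["sex"] == "female", "participant_id"])]
        cyc_f = [p for p in cyc_ids if p in set(female_daily["participant_id"])]
        if cyc_f and len(cyc_f) < female_daily["participant_id"].nunique():
            out["female_minus_cyclic"] = subpopulation_effect(female_daily, cyc_f)
    return out


def _write_comparisons(comparisons: dict, path: Path) -> None:
    payload = {}
    for name, comp in comparisons.items():
        if hasattr(comp, "h") and hasattr(comp, "alpha_corrected"):
            payload[name] = {
                "H": comp.h, "p": comp.p,
                "alpha_corrected": comp.alpha_corrected,
                "significant": comp.significant,
                "medians": comp.medians,
                "effect_sizes": {f"{a}|{b}": es.d_m
                                 for (a, b), es in comp.effect_sizes.items()},
                "larger_median": {f"{a}|{b}": g
                                  for (a, b), g in comp.larger_median.items()},
            }
        else:  # SubpopulationEffect
            payload[name] = {"H": comp.h, "p": comp.p,
                             "whole_larger": comp.whole_larger}
    path.write_text(json.dumps(payload, indent=2))


def _write_gam(selection, table, path: Path) -> None:
    fit = selection.final_fit
    payload = {
        "pseudo_r2_by_interaction_order": selection.pseudo_r2_by_order,
        "main_term_pvalues": selection.main_term_pvalues,
        "dropped_factors": list(selection.dropped),
        "final_pseudo_r2": fit.pseudo_r2,
        "beta0": fit.beta0,
        "effects": {f: dict(e) for f, e in fit.effects.items()},
        "phenotype_predictions": fit.phenotype_predictions().to_dict("records"),
    }
    path.write_text(json.dumps(payload, indent=2, default=float))
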