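"""Orchestration: headline-result reproduction drivers, IO, and manifests.

Every driver chains the library modules under a single seed hierarchy and
writes plain-text tables (TSV/CSV/JSON) plus a run manifest, so each number
in a report is regenerable from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import afo as afo_mod
from . import bayes as bayes_mod
from .psychometrics import (
    SubjectSummary,
    compare_groups,
    fit_dominance_curve,
    summaries_to_frame,
)
from .stimuli import CONDITIONS, ExperimentConfig, TrialSequence, get_condition
from .predictors import label_and_normalize

__all__ = [
    "RunManifest",
    "reproduce",
    "ingest_supplementary",
    "write_summaries",
    "write_trial_log",
    "conditions_to_yaml",
    "config_from_yaml",
]

REPRODUCE_TARGETS = (
    "observer-baseline",
    "afo-cohorts",
    "observer-priors",
    "bifurcation",
    "entrainment",
    "precision-ratio",
)

#: reduced-scale factors: participants / 4, trials / 3
REDUCED_PARTICIPANTS = 15
REDUCED_TRIALS = 100


@dataclass
class RunManifest:
    """Traceability record for one pipeline stage."""

    target: str
    seed: int
    scale: str
    config: dict
    outputs: list[str] = field(default_factory=list)
    started: float = 0.0
    elapsed: float = 0.0
    config_hash: str = ""

    def finalize(self) -> "RunManifest":
        blob = json.dumps(self.config, sort_keys=True, default=str).encode()
        self.config_hash = hashlib.sha256(blob).hexdigest()[:16]
        self.elapsed = time.time() - self.started
        return self

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


def conditions_to_yaml(path) -> None:
    """Write the four standard conditions as a YAML experiment config."""
    out = {
        name: {
            "period_bounds": list(cfg.period_bounds),
            "jitter_sd": cfg.jitter_sd,
            "probe_jitter_frac": cfg.probe_jitter_frac,
            "tone_count_choices": list(cfg.tone_count_choices),
            "n_trials": cfg.n_trials,
            "tone_duration_frac": cfg.tone_duration_frac,
            "sample_rate": cfg.sample_rate,
        }
        for name, cfg in CONDITIONS.items()
    }
    Path(path).write_text(yaml.safe_dump(out, sort_keys=True))


def config_from_yaml(path, name: str) -> ExperimentConfig:
    raw = yaml.safe_load(Path(path).read_text())[name]
    raw["period_bounds"] = tuple(raw["period_bounds"])
    raw["tone_count_choices"] = tuple(raw["tone_count_choices"])
    return ExperimentConfig(condition_name=name, **raw)


def write_summaries(summaries: list[SubjectSummary], path) -> pd.DataFrame:
    df = summaries_to_frame(summaries)
    df.to_csv(path, index=False)
    return df


def read_summaries(path) -> list[SubjectSummary]:
    df = pd.read_csv(path)
    return _frame_to_summaries(df)


def _frame_to_summaries(df: pd.DataFrame) -> list[SubjectSummary]:
    core = {"subject_id", "condition", "slope_abs", "slope_rel", "excluded"}
    out = []
    for _, row in df.iterrows():
        extra = {
            k: row[k]
            for k in df.columns
            if k not in core | {"slope_sum", "slope_diff"}
        }
        out.append(
            SubjectSummary(
                subject_id=str(row.get("subject_id", "")),
                slope_abs=float(row["slope_abs"]),
                slope_rel=float(row["slope_rel"]),
                excluded=bool(row.get("excluded", False)),
                condition=str(row.get("condition", "")),
                extra=extra,
            )
        )
    return out


def write_trial_log(
    trials: list[TrialSequence], path, predictions: bool = True
) -> pd.DataFrame:
    """Trial event log as TSV: one row per trial, tone times in columns."""
    max_tones = max(tr.n_tones for tr in trials)
    rows = []
    for i, tr in enumerate(trials):
        row: dict = {
            "trial_id": i,
            "condition": tr.condition,
            "T": tr.base_period,
            "I": tr.n_tones,
        }
        for j in range(max_tones):
            row[f"t_{j + 1}"] = tr.cue_times[j] if j < tr.n_tones else np.nan
        row["t_probe"] = tr.probe_time
        if predictions:
            pred = label_and_normalize(tr)
            row.update(
                pred_relative=pred.pred_relative,
                pred_absolute=pred.pred_absolute,
                dev_relative_norm=pred.dev_relative_norm,
                dev_absolute_norm=pred.dev_absolute_norm,
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


# ------------------------------------------------------------------ ingest

_ABS_KEYS = ("slope_abs", "slopeabs", "abs", "absolute", "duration")
_REL_KEYS = ("slope_rel", "sloperel", "rel", "relative", "rhythm")


def _match_column(columns, keys) -> str | None:
    low = {str(cname).strip().lower().replace("_", "").replace(" ", ""): cname
           for cname in columns}
    for key in keys:
        k = key.replace("_", "")
        for cand, original in low.items():
            if k in cand:
                return original
    return None


def ingest_supplementary(path) -> tuple[list[SubjectSummary], dict]:
    """Read a per-participant slope table (XLSX or CSV) into summaries.

    The reader looks for one column holding the absolute-algorithm slope and
    one holding the relative-algorithm slope (plus optional condition and
    subject columns), and reports row counts per condition for validation.
    Missing slope columns raise a schema error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        sheets = pd.read_excel(path, sheet_name=None)
        frames = []
        for sheet, df in sheets.items():
            df = df.copy()
            if _match_column(df.columns, _ABS_KEYS) is None:
                continue
            if "condition" not in (c.lower() for c in df.columns.astype(str)):
                df["condition"] = sheet
            frames.append(df)
        if not frames:
            raise ValueError(f"no sheet in {path.name} has recognizable slope columns")
        df = pd.concat(frames, ignore_index=True)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise ValueError(f"{path.name} contains no rows")
    col_abs = _match_column(df.columns, _ABS_KEYS)
    col_rel = _match_column(df.columns, _REL_KEYS)
    if col_abs is None or col_rel is None:
        raise ValueError(
            f"{path.name}: could not locate absolute/relative slope columns "
            f"in {list(df.columns)}"
        )
    col_cond = _match_column(df.columns, ("condition", "experiment", "group"))
    col_id = _match_column(df.columns, ("subject", "participant", "id"))
    col_excl = _match_column(df.columns, ("excluded", "exclude"))
    summaries = []
    for i, row in df.iterrows():
        sa, sr = row[col_abs], row[col_rel]
        if pd.isna(sa) or pd.isna(sr):
            continue
        summaries.append(
            SubjectSummary(
                subject_id=str(row[col_id]) if col_id else f"sub-{i:03d}",
                slope_abs=float(sa),
                slope_rel=float(sr),
                excluded=bool(row[col_excl]) if col_excl else False,
                condition=str(row[col_cond]) if col_cond else "",
            )
        )
    counts = pd.Series([s.condition for s in summaries]).value_counts().to_dict()
    report = {"n_rows": len(df), "n_subjects": len(summaries), "per_condition": counts}
    return summaries, report


# --------------------------------------------------------------- reproduce


def _dominance_report(summaries: list[SubjectSummary]) -> dict:
    fit = fit_dominance_curve(summaries)
    coefs = list(map(float, fit.coefficients))
    return {
        "n_included": int(sum(not s.excluded for s in summaries)),
        "n_excluded": int(sum(s.excluded for s in summaries)),
        "best_order": fit.best_order,
        "aic": {str(k): float(v) for k, v in fit.aic.items()},
        "coefficients": coefs,
        "adj_r_square": fit.adj_r_square,
        "zero_crossing_region": fit.zero_crossing_region,
    }


def reproduce(target: str, scale: str = "reduced", seed: int = 0, outdir="runs") -> dict:
    """Regenerate the quantities behind one headline claim.

    ``scale="reduced"`` cuts cohorts to 15 participants x 100 trials (and
    trims grids) for desk-scale runs; ``"full"`` uses the study sizes
    (60 x 300).  Writes CSV tables and a JSON summary + manifest under
    ``outdir/<target>/`` and returns the summary dict.
    """
    if target not in REPRODUCE_TARGETS:
        raise ValueError(f"unknown target {target!r}; have {REPRODUCE_TARGETS}")
    if scale not in ("full", "reduced"):
        raise ValueError("scale must be 'full' or 'reduced'")
    out = Path(outdir) / target
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        target=target,
        seed=seed,
        scale=scale,
        config={"target": target, "scale": scale, "seed": seed},
        started=time.time(),
    )
    n_part = 60 if scale == "full" else REDUCED_PARTICIPANTS
    n_trials = 300 if scale == "full" else REDUCED_TRIALS
    summary: dict = {"target": target, "scale": scale, "seed": seed}

    if target == "bifurcation":
        res = afo_mod.scan_bifurcation()
        res["table"].to_csv(out / "bifurcation_scan.csv", index=False)
        summary.update(
            onset_rho_e=res["onset"],
            map_constants=res["constants"],
            fit_rel_err=res["fit_rel_err"],
        )
        manifest.outputs.append(str(out / "bifurcation_scan.csv"))

    elif target == "afo-cohorts":
        all_sum: list[SubjectSummary] = []
        per_cond: dict[str, np.ndarray] = {}
        for i, cond in enumerate(("1.2hz", "2hz", "4hz")):
            cohort = afo_mod.CohortConfig(
                condition=cond,
                n_participants=n_part,
                n_trials=n_trials,
                seed=seed * 1000 + i,
            )
            summaries = afo_mod.run_simulated_cohort(cohort)
            write_summaries(summaries, out / f"afo_cohort_{cond}.csv")
            manifest.outputs.append(str(out / f"afo_cohort_{cond}.csv"))
            all_sum.extend(summaries)
            kept = [s.slope_diff for s in summaries if not s.excluded]
            per_cond[cond] = np.asarray(kept)
            summary[f"median_slope_diff_{cond}"] = float(np.median(kept))
        summary["dominance"] = _dominance_report(all_sum)
        compare_groups(per_cond).to_csv(out / "group_tests.csv", index=False)
        manifest.outputs.append(str(out / "group_tests.csv"))

    elif target in ("observer-baseline", "observer-priors"):
        # Bayesian observer cohorts; observer-baseline plays the role of a
        # synthetic "human-like" dataset (absolute prior, absolute noise)
        runs = (
            [("absolute", "absolute"), ("relative", "absolute")]
            if target == "observer-priors"
            else [("absolute", "absolute")]
        )
        if target == "observer-priors":
            runs.append(("absolute", "weber"))
        for prior_type, scaling in runs:
            summaries = bayes_mod.run_observer_experiment(
                prior_type=prior_type,
                noise_scaling=scaling,
                n_observers=n_part,
                n_trials=n_trials,
                seed=seed,
            )
            name = f"bayes_{prior_type}_{scaling}"
            write_summaries(summaries, out / f"{name}.csv")
            manifest.outputs.append(str(out / f"{name}.csv"))
            key = f"dominance_{prior_type}_{scaling}"
            try:
                summary[key] = _dominance_report(summaries)
            except ValueError:
                summary[key] = None

    elif target == "entrainment":
        from .wilson_cowan import (
            CLASSIC_PARAMS,
            PRC_COUPLINGS,
            concentration_at_predictions,
            phase_response_curve,
        )

        rng = np.random.default_rng(seed)
        ks = PRC_COUPLINGS if scale == "full" else (0.02, 0.2, 1.0)
        n_tr = 300 if scale == "full" else 60
        rows = []
        for k in ks:
            for lo, hi in ((0.240, 0.260), (0.210, 0.290)):
                cfg = get_condition("4hz", period_bounds=(lo, hi))
                res = concentration_at_predictions(
                    CLASSIC_PARAMS, cfg, k, rng, n_trials=n_tr, n_permutations=2000
                )
                rows.append(
                    {
                        "k": k,
                        "range": f"{lo:.3f}-{hi:.3f}",
                        "pc_abs": res["pc_abs"],
                        "pc_rel": res["pc_rel"],
                        "p_value": res["p_value"],
                    }
                )
        pc = pd.DataFrame(rows)
        pc.to_csv(out / "phase_concentration.csv", index=False)
        manifest.outputs.append(str(out / "phase_concentration.csv"))
        step = 0.001 if scale == "full" else 0.01
        prc = phase_response_curve(CLASSIC_PARAMS, k_values=ks, onset_step=step)
        prc_rows = []
        for k, d in prc.items():
            prc_rows.append({"k": k, "max_abs_shift": float(np.max(np.abs(d["shifts"])))})
        pd.DataFrame(prc_rows).to_csv(out / "prc_amplitude.csv", index=False)
        manifest.outputs.append(str(out / "prc_amplitude.csv"))
        summary["pc_table"] = pc.to_dict("records")

    elif target == "precision-ratio":
        frames = []
        for jitter in (0.170, 0.045):
            summaries = bayes_mod.run_observer_experiment(
                conditions=("1.2hz",),
                prior_type="absolute",
                noise_scaling="absolute",
                n_observers=n_part,
                n_trials=n_trials,
                seed=seed,
                sigma_exp_override=jitter,
            )
            df = bayes_mod.precision_ratio_analysis(summaries)
            df["jitter"] = jitter
            frames.append(df)
        tab = pd.concat(frames, ignore_index=True)
        tab.to_csv(out / "precision_ratio.csv", index=False)
        manifest.outputs.append(str(out / "precision_ratio.csv"))
        summary["max_ratio"] = float(tab["ratio"].max())

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    manifest.outputs.append(str(out / "summary.json"))
    manifest.finalize().write(out / "manifest.json")
    return summary
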