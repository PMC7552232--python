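"""End-to-end orchestration: one call runs the whole analysis per group.

``run_full_analysis`` takes a :class:`RunConfig` pointing either at
interaction/biometric CSVs or at a synthetic-data config, and writes, per
group: the dyad summary edge list, the Elo trajectory and event log at the
best constant k, the three likelihood optimizations and their comparison
table, the weekly stability series, the cumulative steepness curves and
the daily/weekly size-rank mixed-model results.  A manifest records the
package version, seeds, dialect and the SHA-256 of every output file, so a
re-run with the same config is verifiable byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .elo import EloRating
from .errors import ConfigurationError, ValidationError
from .io import (
    iter_groups,
    read_biometrics,
    read_interactions,
    summarize_dyads,
    write_biometrics,
    write_interactions,
)
from .likelihood import (
    ConstantKMLE,
    PerBehaviorKMLE,
    StartValueMLE,
    compare_models,
)
from .simulate import SyntheticConfig, generate_dataset
from .sizerank import (
    biometric_correlation,
    build_daily_design,
    build_weekly_design,
    fit_mixed_model,
)
from .stability import make_weekly_intervals, stability_series
from .steepness import make_cumulative_periods, steepness_table

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    output_dir: str
    interactions_path: str | None = None
    biometrics_path: str | None = None
    synthetic: SyntheticConfig | None = None
    dialect: str = "normal"
    k_range: tuple = (1.0, 200.0)
    n_grid: int = 200
    n_start_draws: int = 2000
    start_spread: float = 200.0
    n_weekly_intervals: int = 30
    n_monthly_periods: int = 7
    seed: int = 0
    overwrite: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        has_files = self.interactions_path is not None
        if has_files == (self.synthetic is not None):
            raise ConfigurationError(
                "provide either interactions_path (+ optional biometrics_path) "
                "or a synthetic config, not both"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict):
    df.to_csv(path, index=False)
    manifest["files"][path.name] = _sha256(path)


def run_full_analysis(config: RunConfig) -> dict:
    out = Path(config.output_dir)
    if out.exists() and any(out.iterdir()) and not config.overwrite:
        raise ConfigurationError(
            f"output directory {out} is not empty; pass overwrite=True to reuse it"
        )
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "hatchrank",
        "version": __version__,
        "dialect": config.dialect,
        "seed": config.seed,
        "k_range": list(config.k_range),
        "n_grid": config.n_grid,
        "n_start_draws": config.n_start_draws,
        "files": {},
        "groups": {},
    }

    if config.synthetic is not None:
        cohort, interactions, biometrics = generate_dataset(config.synthetic)
        write_interactions(interactions, out / "interactions.csv")
        write_biometrics(biometrics, out / "biometrics.csv")
        manifest["files"]["interactions.csv"] = _sha256(out / "interactions.csv")
        manifest["files"]["biometrics.csv"] = _sha256(out / "biometrics.csv")
        manifest["synthetic_seed"] = config.synthetic.seed
    else:
        interactions = read_interactions(config.interactions_path)
        biometrics = (
            read_biometrics(config.biometrics_path)
            if config.biometrics_path
            else None
        )

    results: dict = {"manifest": manifest, "groups": {}}
    if biometrics is not None and len(biometrics) >= 3:
        r, p, n = biometric_correlation(biometrics)
        manifest["biometric_correlation"] = {"r": r, "p": p, "n": n}

    for stage_idx, (gid, records) in enumerate(iter_groups(interactions)):
        gres: dict = {}
        tag = str(gid)

        summary = summarize_dyads(records)
        _write(summary.to_edge_list(), out / f"dyads_{tag}.csv", manifest)

        const = ConstantKMLE(
            k_range=config.k_range, n_grid=config.n_grid, dialect=config.dialect
        ).fit(records)
        perbeh = PerBehaviorKMLE(
            k_range=config.k_range, n_grid=config.n_grid, dialect=config.dialect
        ).fit(records)
        starts = StartValueMLE(
            k=const.best_k_,
            n_draws=config.n_start_draws,
            spread=config.start_spread,
            dialect=config.dialect,
            random_state=config.seed + stage_idx,
        ).fit(records)
        _write(const.grid_, out / f"k_grid_{tag}.csv", manifest)
        for beh, curve in perbeh.profile_curves_.items():
            _write(curve, out / f"k_profile_{beh}_{tag}.csv", manifest)
        comparison = compare_models(
            [const.result_, perbeh.result_, starts.result_]
        )
        _write(comparison, out / f"model_comparison_{tag}.csv", manifest)

        elo = EloRating(k=const.best_k_, dialect=config.dialect).fit(records)
        traj = elo.daily_scores_.reset_index().melt(
            id_vars="date", var_name="individual", value_name="score"
        )
        traj.insert(0, "group", gid)
        _write(traj, out / f"trajectory_{tag}.csv", manifest)
        events = elo.events_.copy()
        events.insert(0, "group", gid)
        _write(events, out / f"events_{tag}.csv", manifest)

        span = (records["date"].min(), records["date"].max())
        span_days = (span[1] - span[0]).days + 1
        # shorter studies get proportionally fewer intervals/periods
        n_weeks = min(config.n_weekly_intervals, max(1, span_days // 7))
        weekly = make_weekly_intervals(span[0], span[1] + pd.Timedelta(days=1), n_weeks)
        stab = stability_series(elo, weekly, group_id=gid)
        _write(stab, out / f"stability_{tag}.csv", manifest)

        n_periods = min(config.n_monthly_periods, max(1, span_days // 30))
        periods = make_cumulative_periods(span[0], span[1], n_periods)
        steep = steepness_table(elo, periods, group_id=gid)
        _write(steep, out / f"steepness_{tag}.csv", manifest)

        size_rows = []
        if biometrics is not None:
            members = set(records["winner"]).union(records["loser"])
            bio = biometrics[biometrics["individual"].isin(members)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    daily_design = build_daily_design(elo, bio)
                    for predictor in ("scl_diff", "weight_diff"):
                        res = fit_mixed_model(daily_design, "daily", predictor)
                        size_rows.append({"group": gid, **res.to_row()})
                except ValidationError as exc:
                    gres["daily_sizerank_error"] = str(exc)
                try:
                    weekly_design = build_weekly_design(elo, bio, weekly)
                    for predictor in ("scl_diff_max", "weight_diff_max"):
                        res = fit_mixed_model(weekly_design, "weekly", predictor)
                        size_rows.append({"group": gid, **res.to_row()})
                except ValidationError as exc:
                    gres["weekly_sizerank_error"] = str(exc)
            if size_rows:
                _write(pd.DataFrame(size_rows), out / f"sizerank_{tag}.csv", manifest)

        gres.update(
            {
                "n_interactions": int(len(records)),
                "n_individuals": summary.n_individuals,
                "interactions_per_individual": len(records) / summary.n_individuals,
                "unobserved_dyad_proportion": summary.unobserved_dyad_proportion,
                "behavior_proportions": summary.behavior_proportions,
                "best_constant_k": const.best_k_,
                "constant_k_loglik": const.max_loglik_,
                "best_per_behavior_k": perbeh.best_k_,
                "per_behavior_loglik": perbeh.max_loglik_,
                "start_value_loglik": starts.max_loglik_,
                "start_value_baseline_loglik": starts.baseline_loglik_,
            }
        )
        manifest["groups"][tag] = gres
        results["groups"][gid] = {
            "summary": summary,
            "constant_k": const,
            "per_behavior_k": perbeh,
            "start_values": starts,
            "elo": elo,
            "stability": stab,
            "steepness": steep,
            "comparison": comparison,
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return results
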