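"""End-to-end analysis driver: simulate/ingest -> fit -> compare -> predict.

`run_pipeline` chains the package's stages on one dataset: fit the requested
model variants to the group-mean d' trajectories, rank them by AICc,
cross-validate the leading variant against the noise ceiling, refit on
training days only and predict the orientation-transfer session. Every
artifact is written under the output directory together with a provenance
block (seeds, settings), so a rerun with the same configuration reproduces
the numbers exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortSpec, generate_cohort, read_dataset, write_dataset
from .fitting import (
    FitResult,
    SimSettings,
    fit_variant,
    loo_cross_validate,
    predict_transfer,
    session_labels,
)
from .learning import GROUPS, VARIANTS, pack_params, param_names, session_reliabilities
from .fitting import group_phase_for

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: str | Path
    dataset_path: str | Path | None = None
    cohort_spec: CohortSpec | None = None
    variants: tuple[str, ...] = VARIANTS
    fit_sessions: str = "all"  # "all" | "training"
    n_starts: int = 20
    cv_variant: str | None = None  # default: AICc winner
    cv_n_starts: int = 5
    sim: SimSettings = field(default_factory=SimSettings)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("at least one variant must be requested")
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            raise ValueError(f"unknown variants: {sorted(unknown)}")
        if self.fit_sessions not in ("all", "training"):
            raise ValueError("fit_sessions must be 'all' or 'training'")
        if self.dataset_path is None and self.cohort_spec is None:
            raise ValueError("provide a dataset_path or a cohort_spec")


def _sigma_trajectories(fit: FitResult) -> pd.DataFrame:
    """Fitted uncertainty (sigma) per orientation, group and session —
    recomputable from the best-fit parameters alone."""
    rows = []
    labels = session_labels(fit.sim.n_training_sessions, include_test=True)
    for group in GROUPS:
        for label in labels:
            gp = group_phase_for(group, label)
            rel = session_reliabilities(fit.best_params, gp, fit.sim.n_training_sessions)
            rows.append(
                {
                    "variant": fit.variant,
                    "group": group,
                    "session_label": label,
                    "sigma_target": rel.sigma_target,
                    "sigma_distractor": rel.sigma_distractor,
                }
            )
    return pd.DataFrame(rows)


def _fit_to_dict(fit: FitResult) -> dict:
    return {
        "variant": fit.variant,
        "params": dict(zip(param_names(fit.variant), pack_params(fit.best_params).tolist())),
        "sse": fit.sse,
        "n_points": fit.n_points,
        "k": fit.k,
        "aicc": fit.aicc,
        "sessions": list(fit.sessions),
        "base_seed": fit.base_seed,
        "n_starts": len(fit.starts),
        "starts": list(fit.starts),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns it as a dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_rng = np.random.default_rng(config.seed)

    # Stage 1: data.
    if config.dataset_path is not None:
        log.info("stage=data loading %s", config.dataset_path)
        dataset = read_dataset(config.dataset_path)
    else:
        log.info("stage=data simulating cohort (seed=%d)", config.cohort_spec.seed)
        dataset = generate_cohort(config.cohort_spec)
        write_dataset(dataset, out / "dataset.csv")
    fit_sessions = (
        dataset.sessions
        if config.fit_sessions == "all"
        else [s for s in dataset.sessions if s != "OrTest"]
    )

    # Stage 2: fit all variants.
    fits: dict[str, FitResult] = {}
    for variant in config.variants:
        log.info("stage=fit variant=%s n_starts=%d", variant, config.n_starts)
        fits[variant] = fit_variant(
            variant,
            dataset,
            sessions=fit_sessions,
            n_starts=config.n_starts,
            rng=root_rng,
            sim=config.sim,
        )

    # Stage 3: AICc ranking.
    aicc_table = pd.DataFrame(
        [
            {"variant": v, "k": f.k, "sse": f.sse, "aicc": f.aicc}
            for v, f in fits.items()
        ]
    ).sort_values("aicc", ignore_index=True)
    aicc_table["delta_aicc"] = aicc_table["aicc"] - aicc_table["aicc"].min()
    aicc_table.to_csv(out / "aicc_table.csv", index=False)

    # Stage 4: observed vs fitted d' per session.
    means = dataset.group_means(fit_sessions)
    obs_fit = means.rename("observed").reset_index()
    for v, f in fits.items():
        pred = f.predicted_dprimes()
        obs_fit[f"fitted_{v}"] = [
            pred[(g, s)] for g, s in zip(obs_fit["group"], obs_fit["session_label"])
        ]
    obs_fit.to_csv(out / "observed_vs_fitted.csv", index=False)

    # Stage 5: cross-validation with noise ceiling (observer-level data only).
    cv_report = None
    has_observers = len(dataset.observers) > len(GROUPS)
    cv_variant = config.cv_variant or aicc_table["variant"].iloc[0]
    if has_observers:
        log.info("stage=crossval variant=%s", cv_variant)
        cv = loo_cross_validate(
            dataset,
            cv_variant,
            sessions=fit_sessions,
            sim=config.sim,
            rng=root_rng,
            n_starts=config.cv_n_starts,
        )
        cv_report = {
            "variant": cv_variant,
            "mean_r2": cv.mean_r2,
            "sd_r2": cv.sd_r2,
            "ceiling_lower": cv.ceiling_lower,
            "ceiling_upper": cv.ceiling_upper,
            "per_observer_r2": {str(k): v for k, v in cv.per_observer_r2.items()},
            "excluded": [str(x) for x in cv.excluded],
        }

    # Stage 6: training-only fit of the CV variant and transfer prediction.
    training_sessions = [s for s in dataset.sessions if s != "OrTest"]
    log.info("stage=transfer variant=%s", cv_variant)
    fit_train = fit_variant(
        cv_variant,
        dataset,
        sessions=training_sessions,
        n_starts=config.n_starts,
        rng=root_rng,
        sim=config.sim,
    )
    transfer = predict_transfer(
        fit_train, n_trials=config.sim.n_trials, rng=int(root_rng.integers(2**31))
    )
    transfer_report = {"fit": _fit_to_dict(fit_train), "predicted_test_dprime": transfer}
    if "OrTest" in dataset.sessions:
        test_means = dataset.group_means(["OrTest"])
        transfer_report["observed_test_dprime"] = {
            g: float(test_means[(g, "OrTest")]) for g in GROUPS
        }

    # Stage 7: sigma trajectories implied by each fit (the learning curves).
    pd.concat([_sigma_trajectories(f) for f in fits.values()], ignore_index=True).to_csv(
        out / "sigma_trajectories.csv", index=False
    )

    report = {
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "sim": dataclasses.asdict(config.sim),
            "n_starts": config.n_starts,
            "fit_sessions": fit_sessions,
        },
        "fits": {v: _fit_to_dict(f) for v, f in fits.items()},
        "aicc_table": aicc_table.to_dict(orient="records"),
        "crossval": cv_report,
        "transfer": transfer_report,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    log.info("stage=done wrote %s", out / "report.json")
    return report
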