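"""Study orchestration: design -> simulate -> fit -> analyze -> report.

A study is fully described by a :class:`StudyConfig` (parameter ranges,
scenario count, seeds, CV folds, bin and permutation counts) and is
deterministic given its master seed.  Per-scenario results are appended
to the output CSV as they complete, so an interrupted run resumes by
scenario id and produces the same table as an uninterrupted one.

Two presets are provided:

* ``paper-full`` — 10,000 scenarios over the full parameter ranges
  (n in [100, 1000], p in [1001, 40000]); the scale of the original
  cluster study;
* ``desk-small`` — 100 scenarios with n in [100, 500] and
  p in [1001, 5000] (all other ranges full); a single-CPU scaled-down
  reproduction used by the test suite.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dose import datagen, doe, penreg
from dose.doe import ParameterSpace

__all__ = [
    "StudyConfig",
    "PRESETS",
    "make_config",
    "build_design",
    "run_study",
    "saturation_fraction",
    "summarize",
    "StudySummary",
]

log = logging.getLogger("dose")

RESULT_COLUMNS = [
    "scenario_id", "n", "p", "psi", "delta", "rho", "m_true",
    "mse_ridge", "mse_lasso", "mse_enet",
    "lambda_ridge", "alpha_enet", "lambda_lasso", "lambda_enet",
]


@dataclass
class StudyConfig:
    """Everything needed to reproduce a study."""

    seed: int
    n_scenarios: int = 100
    n_candidates: int = 20
    cv_folds: int = 10
    n_range: tuple[int, int] = (100, 1000)
    p_range: tuple[int, int] = (1001, 40000)
    psi_range: tuple[float, float] = (1e-6, 1.0 - 1e-6)
    delta_range: tuple[float, float] = (0.1, 10.0)
    rho_max: float = 0.95
    bins_main: int = 10
    bins_interaction: int = 10
    bins_plot_curves: int = 3
    n_permutations: int = 999
    raw_effect_dist: str = "normal"
    lambda_min_ratio: float = 0.01
    run_analysis: bool = True
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("n_scenarios", "n_candidates", "cv_folds", "bins_main",
                     "bins_interaction", "bins_plot_curves", "n_permutations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def space(self) -> ParameterSpace:
        return ParameterSpace(
            n_range=tuple(self.n_range),
            p_range=tuple(self.p_range),
            psi_range=tuple(self.psi_range),
            delta_range=tuple(self.delta_range),
            rho_range=(0.0, self.rho_max),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "StudyConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("n_range", "p_range", "psi_range", "delta_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


PRESETS: dict[str, dict] = {
    "paper-full": dict(n_scenarios=10000),
    "desk-small": dict(
        n_scenarios=100,
        n_range=(100, 500),
        p_range=(1001, 5000),
        run_analysis=False,
    ),
}


def make_config(preset: str, seed: int, **overrides) -> StudyConfig:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
    kwargs = dict(PRESETS[preset])
    kwargs.update(overrides)
    return StudyConfig(seed=seed, **kwargs)


def build_design(config: StudyConfig) -> pd.DataFrame:
    """Select a maximin LHD and transform it into the scenario table."""
    design = doe.select_best_design(
        config.n_scenarios, 5, config.n_candidates, seed=config.seed
    )
    return doe.transform_design(design, config.space, master_seed=config.seed)


def saturation_fraction(scenarios: pd.DataFrame, rng=None) -> float:
    """Fraction of scenarios whose true model has more features than samples.

    For each scenario the true-model size is a Binomial(p, psi) draw
    made with the scenario's own seed (the same draw the data generator
    would make); no model fitting is involved.
    """
    count = 0
    for row in scenarios.itertuples(index=False):
        r = np.random.default_rng(int(row.seed))
        m_true = r.binomial(int(row.p), float(row.psi))
        if m_true > int(row.n):
            count += 1
    return count / len(scenarios)


def _fit_scenario(scenario: dict, config: StudyConfig) -> dict:
    ds = datagen.generate_dataset(scenario, raw_effect_dist=config.raw_effect_dist)
    # fold assignment seeded per scenario so any row is reproducible alone
    rng = np.random.default_rng(int(scenario["seed"]) + 2**20)
    fits = penreg.fit_all_methods(
        ds, K=config.cv_folds, rng=rng, lambda_min_ratio=config.lambda_min_ratio
    )
    return {
        "scenario_id": int(scenario["scenario_id"]),
        "n": int(scenario["n"]),
        "p": int(scenario["p"]),
        "psi": float(scenario["psi"]),
        "delta": float(scenario["delta"]),
        "rho": float(scenario["rho"]),
        "m_true": ds.m_true,
        "mse_ridge": fits["ridge"].test_mse,
        "mse_lasso": fits["lasso"].test_mse,
        "mse_enet": fits["enet"].test_mse,
        "lambda_ridge": fits["ridge"].chosen_lambda,
        "alpha_enet": fits["enet"].chosen_alpha,
        "lambda_lasso": fits["lasso"].chosen_lambda,
        "lambda_enet": fits["enet"].chosen_lambda,
    }


@dataclass
class StudySummary:
    """Win proportions and saturation summary of a completed study."""

    n_scenarios: int
    win: dict = field(default_factory=dict)  # e.g. {"ridge_over_lasso": 0.9, ...}
    ties: dict = field(default_factory=dict)
    frac_saturated: float = 0.0  # fraction of scenarios with m_true > n

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def summarize(results: pd.DataFrame) -> StudySummary:
    """Pairwise win proportions (strict MSE inequality; ties counted apart)."""
    if len(results) == 0:
        raise ValueError("results table is empty")
    mse = {m: results[f"mse_{m}"].to_numpy(dtype=float) for m in ("ridge", "lasso", "enet")}
    win, ties = {}, {}
    for a, b in (("ridge", "lasso"), ("enet", "ridge"), ("enet", "lasso")):
        win[f"{a}_over_{b}"] = float(np.mean(mse[a] < mse[b]))
        win[f"{b}_over_{a}"] = float(np.mean(mse[b] < mse[a]))
        ties[f"{a}_{b}"] = int(np.sum(mse[a] == mse[b]))
    frac_sat = float(np.mean(results["m_true"].to_numpy() > results["n"].to_numpy()))
    return StudySummary(n_scenarios=len(results), win=win, ties=ties, frac_saturated=frac_sat)


def run_study(config: StudyConfig, out_dir=None, resume: bool = True):
    """Execute all stages of a study; returns (results, summary).

    When ``out_dir`` is given, the design, per-scenario results
    (appended incrementally for resumability), the summary, and — if
    ``config.run_analysis`` — one analysis table per contrast are
    written there.  Scenario failures are logged and recorded as
    missing rows, never imputed.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir) if (
        out_dir is not None or config.out_dir
    ) else None
    scenarios = build_design(config)
    results_path = None
    done: set[int] = set()
    rows: list[dict] = []
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        doe.write_scenarios(scenarios, out / "design.csv")
        config.to_json(out / "config.json")
        results_path = out / "results.csv"
        if resume and results_path.exists():
            prev = pd.read_csv(results_path)
            rows = prev.to_dict("records")
            done = set(prev["scenario_id"].astype(int))
            log.info("resuming: %d scenarios already complete", len(done))
        else:
            results_path.write_text(",".join(RESULT_COLUMNS) + "\n")

    for scenario in scenarios.to_dict("records"):
        sid = int(scenario["scenario_id"])
        if sid in done:
            continue
        t0 = time.time()
        try:
            row = _fit_scenario(scenario, config)
        except Exception:
            log.exception("scenario %d failed; recorded as missing", sid)
            continue
        rows.append(row)
        log.info(
            "scenario %d: n=%d p=%d m_true=%d mse(R/L/E)=%.3f/%.3f/%.3f (%.1fs)",
            sid, row["n"], row["p"], row["m_true"],
            row["mse_ridge"], row["mse_lasso"], row["mse_enet"], time.time() - t0,
        )
        if results_path is not None:
            pd.DataFrame([row])[RESULT_COLUMNS].to_csv(
                results_path, mode="a", header=False, index=False
            )

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS).sort_values("scenario_id")
    results = results.reset_index(drop=True)
    summary = summarize(results)
    if out is not None:
        summary.to_json(out / "summary.json")
    if config.run_analysis and len(results) >= 2 * config.bins_main:
        from dose.dstats import CONTRAST_NAMES, analyze_contrast

        rng = np.random.default_rng(config.seed + 2**24)
        for contrast in CONTRAST_NAMES:
            table = analyze_contrast(
                results, scenarios, contrast, space=config.space,
                G=config.bins_main, G_int=config.bins_interaction,
                B=config.n_permutations, rng=rng,
            )
            if out is not None:
                table.to_csv(out / f"analysis_{contrast}.csv", index=False)
    return results, summary
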