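"""Experiment orchestration: every habitat x sampling scenario, plus null
models and per-point prediction maps.

The full grid fits 19 design scenarios per habitat (interspaced at
10-50 %, one leading aggregated stretch at 10-50 %, and three further
aggregated placements at 20-40 %) and, separately, 10 random-subset null
replicates at each of the five sizes. Predictor subsets are selected once
per habitat on the complete coastline by AIC (``selection_mode="full"``,
the default) or re-selected inside each training sample
(``"per_sample"``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .coastio import CoastlineDataset, write_results
from .hdm_fit import (
    DEFAULT_TERMS,
    DegenerateSampleError,
    FittedHDM,
    build_design,
    fit_logistic,
    predict_prob,
    select_model_aic,
)
from .hdm_eval import evaluate_predictions, null_replicates
from .sampling import SamplingScenario, null_scenarios, scenario_grid, split_for

logger = logging.getLogger(__name__)


@dataclass
class ScenarioResult:
    """One row of the results table: a habitat under one sampling design."""

    habitat: str
    strategy: str
    case: int | None
    fraction: float
    seed: int | None
    n_train: int
    F_train: float
    status: str                      # ok | degenerate | non_converged
    d2: float = float("nan")
    auc: float = float("nan")
    threshold: float = float("nan")
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    accuracy_band: str = ""
    fit: FittedHDM | None = None

    def to_row(self) -> dict:
        return {
            "habitat": self.habitat,
            "strategy": self.strategy,
            "case": self.case if self.case is not None else "",
            "fraction": self.fraction,
            "n_train": self.n_train,
            "F_train": self.F_train,
            "D2": self.d2,
            "AUC": self.auc,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "status": self.status,
        }


def run_scenario(
    dataset: CoastlineDataset,
    habitat: str,
    scenario: SamplingScenario,
    terms: Sequence[str] | None = None,
    selection_mode: str = "full",
    threshold_on: str = "test",
) -> ScenarioResult:
    """Split, fit, predict on the held-out coast, evaluate.

    `terms` are the model terms to fit. With ``selection_mode="full"``
    they should be the subset pre-selected on the complete dataset (pass
    `DEFAULT_TERMS` or the output of `select_terms`); with
    ``"per_sample"`` AIC selection reruns on this training split and
    `terms` act as the candidate pool. A training split with no
    presences (or no absences) yields ``status="degenerate"``.
    `threshold_on` picks where the cut-off is optimised ("test", the
    validation default, or "train").
    """
    if terms is None:
        terms = DEFAULT_TERMS
    y = dataset.habitat(habitat)
    split = split_for(dataset.n, scenario)
    tr = split.train_indices
    te = split.test_indices
    y_tr, y_te = y[tr], y[te]
    base = dict(
        habitat=habitat, strategy=scenario.strategy, case=scenario.case,
        fraction=scenario.fraction, seed=scenario.seed,
        n_train=len(tr), F_train=float(y_tr.mean()),
    )
    try:
        df_tr = dataset.df.iloc[tr]
        if selection_mode == "per_sample":
            fit = select_model_aic(terms, df_tr, y_tr, habitat=habitat)
        else:
            fit = fit_logistic(build_design(df_tr, terms), y_tr, habitat=habitat)
    except DegenerateSampleError:
        return ScenarioResult(**base, status="degenerate")
    probs_te = predict_prob(fit, dataset.df.iloc[te])
    threshold = None
    if threshold_on == "train":
        from .hdm_eval import optimal_threshold
        threshold = optimal_threshold(predict_prob(fit, df_tr), y_tr)
    try:
        ev = evaluate_predictions(probs_te, y_te, threshold=threshold,
                                  train_prevalence=fit.train_prevalence)
    except ValueError:
        return ScenarioResult(**base, status="degenerate", d2=fit.d2, fit=fit)
    status = "ok" if fit.converged else "non_converged"
    return ScenarioResult(
        **base, status=status, d2=fit.d2, auc=ev.auc, threshold=ev.threshold,
        sensitivity=ev.sensitivity, specificity=ev.specificity,
        accuracy_band=ev.accuracy_band, fit=fit,
    )


def select_terms(
    dataset: CoastlineDataset,
    habitat: str,
    candidates: Sequence[str] = DEFAULT_TERMS,
) -> tuple:
    """AIC-selected predictor subset for a habitat on the full coastline."""
    fit = select_model_aic(candidates, dataset.df, dataset.habitat(habitat),
                           habitat=habitat)
    return tuple(fit.selected)


@dataclass
class GridConfig:
    """Configuration of the full experiment grid."""

    habitats: tuple = ()             # default: every habitat in the dataset
    scenarios: tuple = ()            # default: the 19-scenario grid
    selection_mode: str = "full"
    candidates: tuple = DEFAULT_TERMS
    interspaced_k: int = 5
    null_sizes: tuple = (0.10, 0.20, 0.30, 0.40, 0.50)
    null_reps: int = 10
    null_base_seed: int = 20_000

    @classmethod
    def from_file(cls, path) -> "GridConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        scen = tuple(
            SamplingScenario(s["strategy"], s["fraction"], s.get("case"), s.get("seed"))
            for s in raw.get("scenarios", [])
        )
        null = raw.get("null", {})
        return cls(
            habitats=tuple(raw.get("habitats", ())),
            scenarios=scen,
            selection_mode=raw.get("selection_mode", "full"),
            candidates=tuple(raw.get("candidates", DEFAULT_TERMS)),
            interspaced_k=int(raw.get("interspaced_k", 5)),
            null_sizes=tuple(null.get("sizes", (0.10, 0.20, 0.30, 0.40, 0.50))),
            null_reps=int(null.get("reps", 10)),
            null_base_seed=int(null.get("base_seed", 20_000)),
        )


def run_grid(
    dataset: CoastlineDataset,
    config: GridConfig | None = None,
    out_dir=None,
) -> tuple:
    """Run the whole experiment; returns (results_df, null_summary_df).

    Results hold one row per habitat x scenario (status "degenerate" when
    a design misses a rare habitat entirely). Null summaries hold one row
    per habitat x size with replicate means and SDs. When `out_dir` is
    given, ``results.csv`` and ``null_summary.csv`` are written there.
    """
    cfg = config or GridConfig()
    habitats = cfg.habitats or dataset.habitat_codes
    scens = cfg.scenarios or tuple(scenario_grid(dataset.n, cfg.interspaced_k))
    results: list = []
    null_rows: list = []
    for hab in habitats:
        if cfg.selection_mode == "full":
            terms = select_terms(dataset, hab, cfg.candidates)
        else:
            terms = tuple(cfg.candidates)
        logger.info("habitat %s: terms %s", hab, terms)
        for scen in scens:
            res = run_scenario(dataset, hab, scen, terms=terms,
                               selection_mode=cfg.selection_mode)
            results.append(res)
            logger.info("  %s: %s AUC=%.3f", scen.label, res.status, res.auc)
        for frac in cfg.null_sizes:
            try:
                summ = null_replicates(
                    dataset, hab, frac, n_reps=cfg.null_reps,
                    base_seed=cfg.null_base_seed + int(round(frac * 100)),
                    terms=terms,
                    selection_mode="fixed" if cfg.selection_mode == "full" else "per_sample",
                )
            except DegenerateSampleError:
                logger.warning("habitat %s null %.0f%%: all replicates degenerate",
                               hab, frac * 100)
                summ = None
            row = {"habitat": hab, "fraction": frac, "n_reps": cfg.null_reps}
            if summ is None:
                row.update({"n_degenerate": cfg.null_reps})
            else:
                row.update({"n_degenerate": summ.n_degenerate})
                for m in ("d2", "auc", "sensitivity", "specificity"):
                    row[f"{m}_mean"] = summ.mean[m]
                    row[f"{m}_sd"] = summ.sd[m]
            null_rows.append(row)
    results_df = pd.DataFrame([r.to_row() for r in results])
    null_df = pd.DataFrame(null_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_results(results, out_dir / "results.csv")
        null_df.to_csv(out_dir / "null_summary.csv", index=False, float_format="%.4f")
    return results_df, null_df


def binary_map(
    dataset: CoastlineDataset,
    fit: FittedHDM,
    threshold: float,
    train_indices: Sequence[int] = (),
) -> pd.DataFrame:
    """Whole-coast prediction map: probability and binary class per point.

    Class is 1 exactly when probability >= threshold. Rows keep chain
    order; `in_train` tags the points the model was trained on.
    """
    probs = predict_prob(fit, dataset.df)
    in_train = np.zeros(dataset.n, dtype=bool)
    if len(train_indices):
        in_train[np.asarray(list(train_indices), dtype=int)] = True
    out = pd.DataFrame({
        "index": np.arange(dataset.n),
        "x": dataset.df["x"].to_numpy(),
        "y": dataset.df["y"].to_numpy(),
        "probability": probs,
        "predicted": (probs >= threshold).astype(int),
        "in_train": in_train,
    })
    if fit.habitat and fit.habitat in dataset.habitat_codes:
        out["observed"] = dataset.habitat(fit.habitat)
    return out


def write_map_geojson(map_df: pd.DataFrame, path) -> None:
    """Write a binary prediction map as a GeoJSON point collection."""
    feats = []
    for rec in map_df.to_dict("records"):
        props = {k: (float(v) if isinstance(v, (np.floating,)) else
                     int(v) if isinstance(v, (np.integer, bool, np.bool_)) else v)
                 for k, v in rec.items() if k not in ("x", "y")}
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(rec["x"]), float(rec["y"])]},
            "properties": props,
        })
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
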