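"""Classifier evaluation (2-fold CV, pd/pf/accuracy) and pipeline orchestration.

The Bayesian-network risk classifier is scored by 2-fold cross-validation:
regions are split into two stratified folds, the network (structure and
parameters) is learned on each fold and predicts the held-out fold, so every
region is predicted exactly once. Three measures are reported per target
state: *pd*, the probability of detection (recall for the state); *pf*, the
probability of false alarm (rate at which actual other-state regions are
predicted as the state); and *accuracy*, the overall proportion correct.
Metrics are pooled over the two folds' confusion matrices by default;
per-fold averaging is available behind a flag.

:func:`run_pipeline` wires the whole two-stage analysis together on a
synthetic world: weather + factor generation, station-to-region exposure,
per-region Poisson GAM effects, risk labeling and discretization, network
learning, marginal CPTs and cross-validation, with per-stage logging and
intermediate artifacts on disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bn, discretize, exposure, gam, synth

__all__ = [
    "ConfusionMatrix",
    "CvMetrics",
    "confusion_matrix",
    "metrics",
    "stratified_two_fold",
    "two_fold_cv",
    "matrices_matching_metrics",
    "run_pipeline",
    "PipelineError",
]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts from the perspective of one target state.

    ``tp`` = actual state predicted as the state, ``fn`` = actual state
    missed, ``fp`` = actual other-state predicted as the state, ``tn`` =
    actual other-state correctly not predicted.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class CvMetrics:
    """pd / pf / accuracy for one target state; ``None`` marks a metric
    whose denominator was zero (undefined, never reported as 0)."""

    state: str
    pd: float | None
    pf: float | None
    accuracy: float | None


def confusion_matrix(actual, predicted, state: str) -> ConfusionMatrix:
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.shape != predicted.shape or actual.size == 0:
        raise ValueError("actual/predicted must be same-length non-empty")
    is_a = actual == state
    is_p = predicted == state
    return ConfusionMatrix(
        tp=int((is_a & is_p).sum()), fn=int((is_a & ~is_p).sum()),
        fp=int((~is_a & is_p).sum()), tn=int((~is_a & ~is_p).sum()))


def metrics(cm: ConfusionMatrix, state: str) -> CvMetrics:
    """pd = TP/(TP+FN); pf = FP/(FP+TN); accuracy = (TP+TN)/total.

    Accuracy is the same whichever state's matrix is used (same partition
    of the instances)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    pd_ = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else None
    pf_ = cm.fp / (cm.fp + cm.tn) if (cm.fp + cm.tn) else None
    return CvMetrics(state, pd_, pf_, (cm.tp + cm.tn) / cm.total)


def matrices_matching_metrics(total: int, n_actual_state: int, pd_value: float,
                              pf_value: float, decimals: int = 3):
    """All integer confusion matrices on ``total`` instances with
    ``n_actual_state`` actual-state rows whose pd and pf round to the given
    values at ``decimals`` places. Used to check that a reported
    (pd, pf, accuracy) triple is internally consistent."""
    out = []
    n_other = total - n_actual_state
    for tp in range(n_actual_state + 1):
        fn = n_actual_state - tp
        if round(tp / n_actual_state, decimals) != round(pd_value, decimals):
            continue
        for fp in range(n_other + 1):
            tn = n_other - fp
            if round(fp / n_other, decimals) != round(pf_value, decimals):
                continue
            out.append(ConfusionMatrix(tp, fn, fp, tn))
    return out


# ---------------------------------------------------------------------------
# cross-validation


def stratified_two_fold(labels, seed: int) -> np.ndarray:
    """Seeded stratified assignment of rows to folds 0/1.

    Each class is shuffled and split in half; a class's odd remainder goes
    to whichever fold is currently smaller (fold 0 on ties), keeping both
    class proportions and fold sizes balanced to within one region.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    fold = np.full(len(labels), -1, dtype=int)
    sizes = [0, 0]
    for cls in sorted(np.unique(labels).tolist()):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        half, rem = divmod(len(idx), 2)
        first = half + (rem if sizes[0] <= sizes[1] else 0)
        fold[idx[:first]] = 0
        fold[idx[first:]] = 1
        sizes[0] += first
        sizes[1] += len(idx) - first
    return fold


def two_fold_cv(data: pd.DataFrame, target: str, seed: int,
                schedule: bn.SaSchedule | None = None, smoothing: float = 1.0,
                blacklist=(), states: dict | None = None,
                aggregation: str = "pooled"):
    """2-fold cross-validation of the network risk classifier.

    For each fold, structure (simulated annealing) and parameters are
    learned on the *other* fold and the held-out rows are predicted from
    their factor states; every row is predicted exactly once. Returns
    ``(predictions, {state: CvMetrics})``.

    ``aggregation="pooled"`` (default) computes the metrics from the two
    folds' summed confusion matrices; ``"per_fold"`` averages the per-fold
    metrics instead.
    """
    if aggregation not in ("pooled", "per_fold"):
        raise ValueError("aggregation must be 'pooled' or 'per_fold'")
    data = data.reset_index(drop=True)
    cols = [c for c in data.columns if c != "region_id"]
    table = data[cols].astype(str)
    if len(table) < 4:
        raise ValueError("need at least 4 rows for 2-fold CV")
    y = table[target].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both target classes must be present")
    if states is None:
        states = {c: sorted(table[c].unique()) for c in cols}
        if set(states[target]) <= {"low_risk", "high_risk"}:
            # risk nodes list low_risk first so prediction ties stay conservative
            states[target] = [s for s in ("low_risk", "high_risk")
                              if s in states[target]]
    fold = stratified_two_fold(y, seed)
    preds = np.empty(len(table), dtype=object)
    fold_matrices: dict[str, list[ConfusionMatrix]] = {s: [] for s in states[target]}
    for f in (0, 1):
        train = table.loc[fold != f]
        test = table.loc[fold == f]
        if len(np.unique(train[target])) < 2:
            raise ValueError(f"training fold {1 - f} is missing a target class")
        sched = schedule or bn.SaSchedule(seed=seed * 2 + f + 1)
        dag = bn.sa_search(train, sched, blacklist=blacklist, states=states)
        model = bn.fit_cpts(dag, train, smoothing=smoothing)
        for i, row in test.iterrows():
            evidence = {c: row[c] for c in cols if c != target}
            preds[i], _ = bn.predict(model, target, evidence)
        for s in states[target]:
            fold_matrices[s].append(
                confusion_matrix(test[target].to_numpy(),
                                 preds[fold == f], s))
    predictions = pd.DataFrame({
        "region_id": data.get("region_id", pd.RangeIndex(len(data))),
        "actual": y, "predicted": preds, "fold": fold,
    })
    result = {}
    for s in states[target]:
        if aggregation == "pooled":
            pooled = ConfusionMatrix(
                tp=sum(m.tp for m in fold_matrices[s]),
                fn=sum(m.fn for m in fold_matrices[s]),
                fp=sum(m.fp for m in fold_matrices[s]),
                tn=sum(m.tn for m in fold_matrices[s]))
            result[s] = metrics(pooled, s)
        else:
            per = [metrics(m, s) for m in fold_matrices[s]]
            def _avg(vals):
                vals = [v for v in vals if v is not None]
                return float(np.mean(vals)) if vals else None
            result[s] = CvMetrics(s, _avg([m.pd for m in per]),
                                  _avg([m.pf for m in per]),
                                  _avg([m.accuracy for m in per]))
    return predictions, result


# ---------------------------------------------------------------------------
# pipeline orchestration


DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "pipeline_out",
    "inputs": {},                      # optional pre-existing stations/factors CSVs
    "world": {},                       # WorldConfig overrides
    "exposure": {"cell_size": 0.5, "power": 2.0},
    "gam": {"indicator": "tmean"},     # or "auto" for AIC selection
    "bn": {"smoothing": 1.0},
    "cv": {"aggregation": "pooled"},
    # log-rate slopes per degC used when coupling each region's true effect
    # to its sampled risk label (high-risk regions sit above the 1% / 10%
    # labeling thresholds, low-risk ones below)
    "coupling": {"cold": {"low_risk": 0.002, "high_risk": 0.0247},
                 "heat": {"low_risk": 0.0392, "high_risk": 0.1398}},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(config) -> dict:
    """Accepts a dict or a YAML file path; validates against the schema."""
    if isinstance(config, (str, Path)):
        path = Path(config)
        if not path.exists():
            raise PipelineError(f"config file not found: {path}")
        config = yaml.safe_load(path.read_text()) or {}
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise PipelineError(f"unknown config keys: {sorted(unknown)}")
    cfg = _merge(DEFAULT_CONFIG, config)
    if not isinstance(cfg["seed"], int):
        raise PipelineError("config 'seed' must be an integer")
    return cfg


def run_pipeline(config=None) -> dict:
    """Run the full two-stage analysis on a synthetic world.

    Stages: synthetic world -> station-to-region exposure -> per-region
    Poisson GAM percent changes -> risk labels + supervised discretization
    -> network learning (cold and heat) -> marginal CPTs -> 2-fold CV.
    Writes per-stage artifacts under ``out_dir`` and returns their paths
    plus the in-memory results. Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    cfg = load_config(config or {})
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    results: dict = {}

    # ---- stage: synth ----------------------------------------------------
    logger.info("stage synth: generating stations and factor table")
    try:
        world = synth.WorldConfig(seed=cfg["seed"], **cfg["world"])
        factors = synth.generate_factor_table(world)
    except Exception as e:
        raise PipelineError(f"stage 'synth' failed: {e}") from e
    inputs = cfg["inputs"] or {}
    for name in inputs:
        if name not in ("stations", "factors"):
            raise PipelineError(f"stage 'synth': unknown input key {name!r}")
        if not Path(inputs[name]).exists():
            raise PipelineError(
                f"stage 'synth': missing input {name!r} CSV at {inputs[name]}")
    if "stations" in inputs:
        stations_path = Path(inputs["stations"])
    else:
        stations_path = out / "stations.csv"
        synth.generate_stations(world).to_csv(stations_path, index=False)
    if "factors" in inputs:
        factors_path = Path(inputs["factors"])
        factors.continuous = pd.read_csv(factors_path)
    else:
        factors_path = out / "factors.csv"
        factors.continuous.to_csv(factors_path, index=False)
        factors.discrete.to_csv(out / "factors_discrete.csv", index=False)
    artifacts["stations"] = str(stations_path)
    artifacts["factors"] = str(factors_path)

    # ---- stage: exposure -------------------------------------------------
    logger.info("stage exposure: IDW + zonal aggregation for %d regions",
                world.n_regions)
    for name, path in (("stations", stations_path), ("factors", factors_path)):
        if not path.exists():
            raise PipelineError(f"stage 'exposure': missing input {name} CSV at {path}")
    try:
        cell = float(cfg["exposure"]["cell_size"])
        ext = synth.EXTENT
        grid = exposure.Grid(ext["lon_min"], ext["lat_min"], cell,
                             int(np.ceil((ext["lon_max"] - ext["lon_min"]) / cell)),
                             int(np.ceil((ext["lat_max"] - ext["lat_min"]) / cell)))
        masks = synth.region_box_masks(world, grid)
        station_df = pd.read_csv(stations_path)
        region_weather = exposure.build_region_series(
            station_df, grid, masks, power=cfg["exposure"]["power"])
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(f"stage 'exposure' failed: {e}") from e
    region_series_path = out / "region_series.csv"

    # ---- stage: mortality (synthetic truth coupled to sampled labels) ----
    logger.info("stage synth-mortality: drawing deaths per region")
    try:
        couple = cfg["coupling"]
        labels = factors.labels.set_index("region_id")
        series_frames = []
        for rid, grp in region_weather.groupby("region_id"):
            bc = couple["cold"][labels.loc[rid, "cold_risk"]]
            bh = couple["heat"][labels.loc[rid, "heat_risk"]]
            series_frames.append(
                synth.generate_mortality(grp, world, beta_cold=bc, beta_heat=bh))
        region_series = pd.concat(series_frames, ignore_index=True)
    except Exception as e:
        raise PipelineError(f"stage 'synth-mortality' failed: {e}") from e
    region_series.to_csv(region_series_path, index=False)
    artifacts["region_series"] = str(region_series_path)

    # ---- stage: gam ------------------------------------------------------
    logger.info("stage gam: per-region percent changes")
    try:
        effect_rows = []
        effects: dict[str, dict[str, gam.EffectEstimate]] = {"cold": {}, "heat": {}}
        for rid, grp in region_series.groupby("region_id"):
            for side in ("cold", "heat"):
                indicator = cfg["gam"]["indicator"]
                if indicator == "auto":
                    indicator, _ = gam.select_indicator_by_aic(grp, side)
                est = gam.estimate_effects(grp, side, region_id=rid,
                                           indicator=indicator)
                effects[side][rid] = est
                effect_rows.append({
                    "region_id": rid, "side": side, "indicator": est.indicator,
                    "tau": est.tau, "beta_total": est.beta_total, "se": est.se,
                    "percent_change": est.percent_change, "floored": est.floored,
                })
    except Exception as e:
        raise PipelineError(f"stage 'gam' failed: {e}") from e
    effects_path = out / "effects.csv"
    pd.DataFrame(effect_rows).to_csv(effects_path, index=False)
    artifacts["effects"] = str(effects_path)

    # ---- stage: discretize ----------------------------------------------
    logger.info("stage discretize: risk labels and factor states")
    try:
        cont = factors.continuous
        tables = {}
        for side in ("cold", "heat"):
            lab = pd.Series(
                [discretize.label_risk(effects[side][rid]) for rid in cont["region_id"]],
                index=cont.index)
            if lab.nunique() < 2:
                raise ValueError(f"{side}: all regions share one risk class; "
                                 "supervised discretization undefined")
            scheme = discretize.build_scheme(cont, lab)
            disc = discretize.apply_scheme(cont, scheme)
            disc[f"{side}_risk"] = lab
            tables[side] = (disc, scheme)
            (out / f"scheme_{side}.json").write_text(scheme.to_json())
            disc.to_csv(out / f"training_table_{side}.csv", index=False)
            artifacts[f"training_table_{side}"] = str(out / f"training_table_{side}.csv")
    except Exception as e:
        raise PipelineError(f"stage 'discretize' failed: {e}") from e

    # ---- stage: bn -------------------------------------------------------
    logger.info("stage bn: structure + parameter learning")
    try:
        models = {}
        marginal_rows = []
        for side in ("cold", "heat"):
            disc, _ = tables[side]
            target = f"{side}_risk"
            cols = [c for c in disc.columns if c != "region_id"]
            table = disc[cols].astype(str)
            states = {c: sorted(table[c].unique()) for c in cols}
            states[target] = ["low_risk", "high_risk"]
            sched = bn.SaSchedule(seed=cfg["seed"] + (1 if side == "cold" else 2))
            dag = bn.sa_search(table, sched, states=states)
            model = bn.fit_cpts(dag, table, smoothing=cfg["bn"]["smoothing"])
            models[side] = model
            (out / f"bn_{side}.json").write_text(model.to_json())
            (out / f"bn_{side}.dot").write_text(model.to_dot())
            artifacts[f"bn_{side}"] = str(out / f"bn_{side}.json")
            # factors with a direct link to the target, either direction
            neighbors = sorted(set(model.dag.parents(target))
                               | {v for u, v in model.dag.edges if u == target})
            for factor in neighbors:
                mc = bn.marginal_cpt(model, target, factor)
                for st in mc.index:
                    marginal_rows.append({
                        "side": side, "factor": factor, "factor_state": st,
                        "p_low_risk": mc.loc[st, "low_risk"],
                        "p_high_risk": mc.loc[st, "high_risk"],
                    })
        marginals = pd.DataFrame(
            marginal_rows, columns=["side", "factor", "factor_state",
                                    "p_low_risk", "p_high_risk"])
        marginals.to_csv(out / "marginal_cpts.csv", index=False)
        artifacts["marginal_cpts"] = str(out / "marginal_cpts.csv")
    except Exception as e:
        raise PipelineError(f"stage 'bn' failed: {e}") from e

    # ---- stage: cv -------------------------------------------------------
    logger.info("stage cv: 2-fold cross-validation")
    try:
        cv_rows = []
        cv_results = {}
        for side in ("cold", "heat"):
            disc, _ = tables[side]
            target = f"{side}_risk"
            preds, mets = two_fold_cv(
                disc, target, seed=cfg["seed"],
                smoothing=cfg["bn"]["smoothing"],
                aggregation=cfg["cv"]["aggregation"])
            cv_results[side] = (preds, mets)
            for s, m in mets.items():
                cv_rows.append({"side": side, "state": s, "pd": m.pd,
                                "pf": m.pf, "accuracy": m.accuracy})
        cv_df = pd.DataFrame(cv_rows)
        cv_df.to_csv(out / "cv_metrics.csv", index=False)
        artifacts["cv_metrics"] = str(out / "cv_metrics.csv")
    except Exception as e:
        raise PipelineError(f"stage 'cv' failed: {e}") from e

    # ---- report ----------------------------------------------------------
    lines = ["Temperature-mortality pipeline report", "=" * 40, ""]
    lines.append("Per-region percent change per 1 degC beyond threshold:")
    for row in effect_rows:
        lines.append(f"  {row['region_id']} {row['side']:4s}: "
                     f"{row['percent_change']:6.2f}% (se of slope {row['se']:.4f}"
                     f"{', floored' if row['floored'] else ''})")
    for side in ("cold", "heat"):
        lines.append("")
        lines.append(f"{side} network edges: {models[side].dag.edges}")
        lines.append(f"{side} 2-fold CV:")
        for s, m in cv_results[side][1].items():
            fmt = lambda v: "undefined" if v is None else f"{v:.3f}"
            lines.append(f"  {s}: pd={fmt(m.pd)} pf={fmt(m.pf)} "
                         f"accuracy={fmt(m.accuracy)}")
    report_path = out / "report.txt"
    report_path.write_text("\n".join(lines) + "\n")
    artifacts["report"] = str(report_path)

    results.update(effects=effects, models=models, cv=cv_results,
                   marginals=marginals, factors=factors)
    return {"artifacts": artifacts, "results": results, "config": cfg}
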