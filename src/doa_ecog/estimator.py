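"""Lagged-feature gradient-boosting estimation of anesthetic depth.

The estimator never sees the hidden depth: its targets are observable proxies
(administered isoflurane concentration, evoked-response attenuation, or — for
the confound control — elapsed time). Inputs are the feature vectors of the
three most recent 10 s windows (t-2, t-1, t-0), stacked per row; rows never
span block boundaries or discarded intervals, so no input mixes
concentrations. Evaluation is leave-one-animal-out: each fold trains on all
other animals and is scored on the held-out one, with regression metrics,
nearest-level quantized classification metrics (isoflurane target), and
normalized split-gain (Gini-gain) feature importances per fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import GradientBoostingRegressor

from .evoked import attach_era
from .features import FeatureConfig, extract_feature_table, feature_columns
from .preprocess import preprocess_recording, segment_blocks
from .synthetic_data import Recording

__all__ = [
    "EstimatorConfig",
    "LaggedDataset",
    "FoldResult",
    "ExperimentResult",
    "assemble_dataset",
    "loo_folds",
    "fit_boosted_regressor",
    "evaluate_regression",
    "quantize_predictions",
    "classification_metrics",
    "feature_importances",
    "time_control",
    "permute_targets_within_animals",
    "run_doa_experiment",
]

ISOFLURANE_LEVELS = (1.0, 1.5, 2.3)


@dataclass(frozen=True)
class EstimatorConfig:
    steps: int = 100
    max_depth: int = 3
    learning_rate: float = 0.1
    lags: int = 3
    min_train_rows: int = 50
    levels: tuple[float, ...] = ISOFLURANE_LEVELS
    seed: int = 0


@dataclass
class LaggedDataset:
    """Rows of lag-stacked feature vectors with a target and animal labels."""

    X: pd.DataFrame  # columns like "coherence_5_40_t-2"
    y: np.ndarray
    animals: np.ndarray
    times_s: np.ndarray
    target: str

    def __len__(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)


@dataclass
class FoldResult:
    animal_id: str
    times_s: np.ndarray
    y_true: np.ndarray
    y_pred: np.ndarray
    mae: float
    r2: float
    importances: pd.Series
    classification: dict[str, float] | None = None


@dataclass
class ExperimentResult:
    target: str
    folds: list[FoldResult]
    summary: dict[str, float]
    time_control: dict[str, float] | None = None
    feature_table: pd.DataFrame | None = None

    def predictions_frame(self, smooth_windows: int = 6) -> pd.DataFrame:
        """Per-row held-out predictions with a trailing "standard error of the
        past minute" band (6 consecutive 10 s windows by default)."""
        frames = []
        for fold in self.folds:
            err = fold.y_pred - fold.y_true
            se = np.array(
                [
                    err[max(0, i - smooth_windows + 1) : i + 1].std()
                    for i in range(err.size)
                ]
            )
            frames.append(
                pd.DataFrame(
                    {
                        "animal_id": fold.animal_id,
                        "t_s": fold.times_s,
                        "y": fold.y_true,
                        "y_hat": fold.y_pred,
                        "se_past_min": se,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def assemble_dataset(
    table: pd.DataFrame, target: str = "isoflurane", lags: int = 3
) -> LaggedDataset:
    """Stack each window's features with its lags-1 predecessors.

    Rows are built only inside contiguous runs (one block of one animal), so
    no input spans a discarded interval or concentration change. ``target``
    selects the label column: "isoflurane" (administered concentration),
    "era", or "time" (elapsed seconds, for the confound control).
    """
    target_col = {"isoflurane": "concentration", "era": "era", "time": "t_start_s"}[target]
    if target_col not in table.columns:
        raise ValueError(f"table lacks the '{target_col}' column needed for target={target}")
    feats = feature_columns(table)
    xs, ys, animals, times = [], [], [], []
    for (_animal, _segment), grp in table.groupby(["animal_id", "segment_index"], sort=False):
        grp = grp.sort_values("window_index")
        f = grp[feats].to_numpy()
        tgt = grp[target_col].to_numpy()
        for n in range(lags - 1, len(grp)):
            if np.isnan(tgt[n]):
                continue
            xs.append(np.concatenate([f[n - lags + 1 + k] for k in range(lags)]))
            ys.append(tgt[n])
            animals.append(grp["animal_id"].iloc[n])
            times.append(grp["t_start_s"].iloc[n])
    names = [
        f"{name}_t-{lags - 1 - k}" for k in range(lags) for name in feats
    ]
    if not xs:
        warnings.warn("no contiguous runs of sufficient length; dataset is empty")
        X = pd.DataFrame(np.empty((0, len(names))), columns=names)
        return LaggedDataset(X, np.empty(0), np.empty(0, dtype=object), np.empty(0), target)
    X = pd.DataFrame(np.vstack(xs), columns=names)
    return LaggedDataset(
        X, np.array(ys, dtype=float), np.array(animals, dtype=object), np.array(times), target
    )


def loo_folds(dataset: LaggedDataset) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Leave-one-animal-out splits: (held-out animal, train rows, eval rows)."""
    animals = pd.unique(dataset.animals)
    if animals.size < 2:
        raise ValueError("leave-one-animal-out needs at least 2 animals")
    folds = []
    for animal in animals:
        eval_idx = np.flatnonzero(dataset.animals == animal)
        train_idx = np.flatnonzero(dataset.animals != animal)
        folds.append((str(animal), train_idx, eval_idx))
    return folds


def fit_boosted_regressor(
    X: pd.DataFrame,
    y: np.ndarray,
    steps: int = 100,
    max_depth: int = 3,
    learning_rate: float = 0.1,
    seed: int = 0,
    min_train_rows: int = 50,
) -> GradientBoostingRegressor:
    """Stagewise least-squares boosting of depth-limited regression trees."""
    if len(X) < min_train_rows:
        raise ValueError(f"need >= {min_train_rows} training rows, got {len(X)}")
    model = GradientBoostingRegressor(
        loss="squared_error",
        n_estimators=steps,
        max_depth=max_depth,
        learning_rate=learning_rate,
        random_state=seed,
    )
    model.fit(X.to_numpy(), np.asarray(y, dtype=float))
    return model


def evaluate_regression(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """MAE and R^2 (R^2 about the eval-set mean; NaN if the target is constant)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0:
        raise ValueError("empty evaluation set")
    mae = float(np.mean(np.abs(y_pred - y_true)))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst == 0:
        return mae, float("nan")
    sse = float(np.sum((y_true - y_pred) ** 2))
    return mae, 1.0 - sse / sst


def quantize_predictions(
    y_pred: np.ndarray, levels: tuple[float, ...] = ISOFLURANE_LEVELS
) -> np.ndarray:
    """Nearest-level quantization; midpoint ties resolve to the lower level."""
    levels_arr = np.asarray(sorted(levels), dtype=float)
    d = np.abs(np.asarray(y_pred, dtype=float)[:, None] - levels_arr[None, :])
    return levels_arr[np.argmin(d, axis=1)]


def classification_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    levels: tuple[float, ...] = ISOFLURANE_LEVELS,
) -> dict[str, float]:
    """One-vs-all confusion metrics per level, macro-averaged (unweighted).

    Levels absent from both truth and predictions are excluded from the macro
    average with a warning.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    n = y_true.size
    accs, precs, recs, f1s = [], [], [], []
    for level in sorted(levels):
        t = np.isclose(y_true, level)
        p = np.isclose(y_pred, level)
        if not t.any() and not p.any():
            warnings.warn(f"level {level} absent from truth and predictions; excluded")
            continue
        tp = float(np.sum(t & p))
        tn = float(np.sum(~t & ~p))
        fp = float(np.sum(~t & p))
        fn = float(np.sum(t & ~p))
        accs.append((tp + tn) / n)
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        precs.append(prec)
        recs.append(rec)
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0)
    return {
        "accuracy": float(np.mean(accs)),
        "precision": float(np.mean(precs)),
        "recall": float(np.mean(recs)),
        "f1": float(np.mean(f1s)),
    }


def feature_importances(model: GradientBoostingRegressor, names: list[str]) -> pd.Series:
    """Normalized total split-gain (Gini gain) per lagged feature, descending."""
    # clip float-noise negatives from the library's impurity accounting
    imp = pd.Series(np.clip(model.feature_importances_, 0.0, None), index=names)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return imp.sort_values(ascending=False)


def permute_targets_within_animals(
    dataset: LaggedDataset, rng: np.random.Generator
) -> LaggedDataset:
    """Null control: shuffle targets across time within each animal."""
    y = dataset.y.copy()
    for animal in pd.unique(dataset.animals):
        idx = np.flatnonzero(dataset.animals == animal)
        y[idx] = rng.permutation(y[idx])
    return LaggedDataset(dataset.X, y, dataset.animals, dataset.times_s, dataset.target)


def _run_folds(
    dataset: LaggedDataset, cfg: EstimatorConfig, with_classification: bool
) -> list[FoldResult]:
    folds = []
    for animal, train_idx, eval_idx in loo_folds(dataset):
        model = fit_boosted_regressor(
            dataset.X.iloc[train_idx],
            dataset.y[train_idx],
            cfg.steps,
            cfg.max_depth,
            cfg.learning_rate,
            cfg.seed,
            cfg.min_train_rows,
        )
        y_pred = model.predict(dataset.X.iloc[eval_idx].to_numpy())
        y_true = dataset.y[eval_idx]
        mae, r2 = evaluate_regression(y_true, y_pred)
        cls = None
        if with_classification:
            cls = classification_metrics(
                quantize_predictions(y_true, cfg.levels),
                quantize_predictions(y_pred, cfg.levels),
                cfg.levels,
            )
        folds.append(
            FoldResult(
                animal_id=animal,
                times_s=dataset.times_s[eval_idx],
                y_true=y_true,
                y_pred=y_pred,
                mae=mae,
                r2=r2,
                importances=feature_importances(model, dataset.feature_names),
                classification=cls,
            )
        )
    return folds


def time_control(
    table: pd.DataFrame, doa_fold_r2: dict[str, float], cfg: EstimatorConfig
) -> dict[str, float]:
    """Confound control: train the identical regressor on elapsed time and
    Spearman-correlate its per-fold R^2 with the depth-target per-fold R^2.

    A significant positive correlation would suggest the depth estimator is
    exploiting elapsed time rather than anesthetic state.
    """
    time_ds = assemble_dataset(table, target="time", lags=cfg.lags)
    time_folds = _run_folds(time_ds, cfg, with_classification=False)
    time_r2 = {f.animal_id: f.r2 for f in time_folds}
    animals = [a for a in doa_fold_r2 if a in time_r2]
    if len(animals) < 3:
        raise ValueError("time control needs at least 3 folds")
    rho, p = sps.spearmanr([doa_fold_r2[a] for a in animals], [time_r2[a] for a in animals])
    return {
        "spearman_rho": float(rho),
        "p_value": float(p),
        "mean_time_r2": float(np.mean(list(time_r2.values()))),
    }


def build_feature_table(
    recordings: list[Recording],
    feat_cfg: FeatureConfig | None = None,
    discard_minutes: float = 5.0,
    with_era: bool = False,
    era_window_stimuli: int = 10,
) -> pd.DataFrame:
    """Preprocess, segment, and featurize a cohort into one table."""
    feat_cfg = feat_cfg or FeatureConfig()
    tables = []
    for rec in recordings:
        clean = preprocess_recording(rec)
        blocks = segment_blocks(clean, discard_minutes)
        table = extract_feature_table(blocks, feat_cfg)
        if with_era:
            table = attach_era(
                table, clean, blocks, era_window_stimuli, window_s=feat_cfg.window_s
            )
        tables.append(table)
    return pd.concat(tables, ignore_index=True)


def run_doa_experiment(
    recordings: list[Recording],
    target: str = "isoflurane",
    est_cfg: EstimatorConfig | None = None,
    feat_cfg: FeatureConfig | None = None,
    discard_minutes: float = 5.0,
    with_time_control: bool = True,
    feature_table: pd.DataFrame | None = None,
) -> ExperimentResult:
    """Full pipeline: preprocess -> features (-> ERA) -> lagged dataset ->
    leave-one-animal-out boosting -> metrics, importances, time control."""
    if feature_table is None and len(recordings) < 2:
        raise ValueError("need at least 2 recordings")
    est_cfg = est_cfg or EstimatorConfig()
    if feature_table is None:
        feature_table = build_feature_table(
            recordings, feat_cfg, discard_minutes, with_era=(target == "era")
        )
    dataset = assemble_dataset(feature_table, target=target, lags=est_cfg.lags)
    folds = _run_folds(dataset, est_cfg, with_classification=(target == "isoflurane"))
    summary: dict[str, float] = {
        "mae_mean": float(np.mean([f.mae for f in folds])),
        "mae_std": float(np.std([f.mae for f in folds])),
        "r2_mean": float(np.nanmean([f.r2 for f in folds])),
        "r2_std": float(np.nanstd([f.r2 for f in folds])),
        "n_folds": float(len(folds)),
        "n_rows": float(len(dataset)),
    }
    if target == "isoflurane":
        for metric in ("accuracy", "f1", "precision", "recall"):
            vals = [f.classification[metric] for f in folds]
            summary[f"{metric}_mean"] = float(np.mean(vals))
            summary[f"{metric}_std"] = float(np.std(vals))
    control = None
    if with_time_control and len(folds) >= 3:
        control = time_control(feature_table, {f.animal_id: f.r2 for f in folds}, est_cfg)
    return ExperimentResult(
        target=target,
        folds=folds,
        summary=summary,
        time_control=control,
        feature_table=feature_table,
    )
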