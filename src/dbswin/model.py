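"""Nested feature selection and gradient-boosted regression under LOEO.

The prediction target is the normalized therapeutic window of each contact.
Evaluation is leave-one-electrode-out (LOEO): all contacts of one electrode
form the test fold while every other electrode trains the model.  Feature
selection (Boruta against shadow features, consensus over bootstrap
resamples of training electrodes) and hyperparameter tuning (tree count by
grouped cross-validation, then a seeded random search over the boosted-tree
space) are nested inside each fold, so no information from the held-out
electrode leaks into its fold's model.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GroupKFold
from xgboost import XGBRegressor

log = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "SelectionResult",
    "ModelBundle",
    "boruta_select",
    "consensus_select",
    "tune_hyperparameters",
    "loeo_predict",
    "train_full_and_apply",
]


@dataclass(frozen=True)
class ModelConfig:
    """Budgets and search space of the nested selection/tuning machinery."""

    boruta_max_rounds: int = 100
    boruta_rf_trees: int = 100
    boruta_alpha: float = 0.05
    consensus_resamples: int = 10
    keep_threshold: int = 7
    stage1_max_trees: int = 500
    stage1_early_stopping: int = 20
    tune_cv_folds: int = 10
    tune_evals: int = 25
    # search-space bounds (overridable)
    space: dict = field(
        default_factory=lambda: {
            "max_depth": (2, 8),
            "learning_rate": (0.01, 0.3),  # log-uniform
            "subsample": (0.5, 1.0),
            "colsample_bytree": (0.3, 1.0),
            "min_child_weight": (1, 10),
            "reg_alpha": (0.0, 5.0),
            "reg_lambda": (0.0, 5.0),
        }
    )

    @staticmethod
    def reduced() -> "ModelConfig":
        """Smaller budget for demonstration-scale cohorts."""
        return ModelConfig(
            boruta_max_rounds=15, boruta_rf_trees=50,
            stage1_max_trees=300, tune_cv_folds=4, tune_evals=8,
        )


@dataclass
class SelectionResult:
    """Per-fold selected features and the global selection frequency."""

    per_fold: dict  # fold label -> list of selected feature names
    frequency: pd.Series  # feature -> fraction of folds selecting it
    params_per_fold: dict = field(default_factory=dict)  # fold -> hyperparams


@dataclass
class ModelBundle:
    """A fitted boosted-tree model plus everything needed to reapply it."""

    model: XGBRegressor
    hyperparameters: dict
    selected_features: list
    training_cohort: str
    seed: int

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        import xgboost as xgb

        missing = [f for f in self.selected_features if f not in X.columns]
        if missing:
            raise ValueError(f"missing feature columns: {missing}")
        data = X[self.selected_features].to_numpy()
        if isinstance(self.model, xgb.Booster):
            return self.model.predict(xgb.DMatrix(data))
        return self.model.predict(data)

    def save(self, path) -> None:
        from pathlib import Path

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        booster = (self.model.get_booster()
                   if hasattr(self.model, "get_booster") else self.model)
        booster.save_model(path / "model.json")
        meta = dict(
            hyperparameters=self.hyperparameters,
            selected_features=list(self.selected_features),
            training_cohort=self.training_cohort,
            seed=self.seed,
        )
        (path / "meta.json").write_text(json.dumps(meta, indent=2))

    @staticmethod
    def load(path) -> "ModelBundle":
        from pathlib import Path

        import xgboost as xgb

        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        booster = xgb.Booster()
        booster.load_model(str(path / "model.json"))
        return ModelBundle(model=booster, seed=meta["seed"], **{
            k: meta[k] for k in
            ("hyperparameters", "selected_features", "training_cohort")
        })


def _xgb(params: dict, seed: int) -> XGBRegressor:
    return XGBRegressor(
        objective="reg:squarederror", tree_method="hist", n_jobs=1,
        random_state=int(seed) % (2**31), verbosity=0, **params,
    )


def boruta_select(
    X: pd.DataFrame,
    y,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> list:
    """All-relevant feature selection against shadow features.

    Each round appends a column-shuffled shadow copy of every surviving
    feature, fits a random forest, and scores a "hit" for features whose
    impurity importance exceeds the best shadow importance.  Hits are tested
    against Binomial(rounds, 1/2) two-sided at ``boruta_alpha``: features
    significantly above chance are confirmed, significantly below rejected
    (and dropped from subsequent rounds).  Features still undecided when the
    round budget is exhausted are rejected (conservative).  Returns the
    confirmed features in original column order.
    """
    cfg = config or ModelConfig()
    y = np.asarray(y, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 rows")
    if np.std(y) == 0:
        raise ValueError("constant target")

    rng = np.random.default_rng(seed)
    cols = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    tentative = list(range(len(cols)))
    confirmed: list[int] = []
    hits = np.zeros(len(cols), dtype=int)
    alpha2 = cfg.boruta_alpha / 2.0

    for round_no in range(1, cfg.boruta_max_rounds + 1):
        if not tentative:
            break
        design_idx = confirmed + tentative
        design = Xv[:, design_idx]
        shadows = design.copy()
        for j in range(shadows.shape[1]):
            rng.shuffle(shadows[:, j])
        rf = RandomForestRegressor(
            n_estimators=cfg.boruta_rf_trees, max_features="sqrt",
            random_state=int(rng.integers(2**31)), n_jobs=1,
        )
        rf.fit(np.hstack([design, shadows]), y)
        imp = rf.feature_importances_
        shadow_max = imp[design.shape[1]:].max()
        real_imp = imp[: design.shape[1]]
        for pos, fi in enumerate(design_idx):
            if fi in tentative and real_imp[pos] > shadow_max:
                hits[fi] += 1

        still = []
        for fi in tentative:
            h = hits[fi]
            if binom.sf(h - 1, round_no, 0.5) < alpha2:
                confirmed.append(fi)
            elif binom.cdf(h, round_no, 0.5) < alpha2:
                pass  # rejected: drop from design
            else:
                still.append(fi)
        tentative = still

    return [cols[i] for i in sorted(confirmed)]


def consensus_select(
    X: pd.DataFrame,
    y,
    electrodes,
    seed: int = 0,
    n_resamples: int | None = None,
    keep_threshold: int | None = None,
    config: ModelConfig | None = None,
) -> list:
    """Robust feature set: Boruta over bootstrap resamples of electrodes.

    Whole electrodes are resampled with replacement (contacts of one
    electrode always travel together), Boruta runs once per resample, and
    features confirmed in at least ``keep_threshold`` of ``n_resamples``
    runs are kept.  An empty consensus falls back to the full feature set
    with a loud warning rather than an unfittable model.
    """
    cfg = config or ModelConfig()
    n_resamples = n_resamples or cfg.consensus_resamples
    keep_threshold = keep_threshold or cfg.keep_threshold
    electrodes = pd.Series(list(electrodes), index=X.index)
    unique = sorted(electrodes.unique())
    ss = np.random.SeedSequence(seed)
    resample_rng = np.random.default_rng(ss.spawn(1)[0])
    boruta_seeds = [int(s.generate_state(1)[0] % (2**31))
                    for s in ss.spawn(n_resamples)]

    counts: dict[str, int] = {}
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    for r in range(n_resamples):
        sampled = resample_rng.choice(len(unique), size=len(unique), replace=True)
        rows = []
        for k in sampled:
            rows.append(X.index[electrodes == unique[k]])
        row_index = rows[0].append(rows[1:]) if len(rows) > 1 else rows[0]
        Xb = X.loc[row_index]
        yb = y.loc[row_index]
        for f in boruta_select(Xb, yb, seed=boruta_seeds[r], config=cfg):
            counts[f] = counts.get(f, 0) + 1

    kept = [c for c in X.columns if counts.get(c, 0) >= keep_threshold]
    if not kept:
        msg = ("consensus feature selection returned no features; "
               "falling back to the full feature set")
        log.warning(msg)
        warnings.warn(msg, stacklevel=2)
        kept = list(X.columns)
    return kept


def _grouped_folds(electrodes, n_splits: int):
    groups = np.asarray(electrodes)
    n_groups = len(np.unique(groups))
    if n_groups < n_splits:
        warnings.warn(
            f"only {n_groups} electrodes; reducing CV folds from {n_splits}",
            stacklevel=2,
        )
        n_splits = max(2, n_groups)
    return GroupKFold(n_splits=n_splits), groups


def tune_hyperparameters(
    X: pd.DataFrame,
    y,
    electrodes,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> dict:
    """Two-stage nested tuning on the training set only.

    Stage 1 picks the tree count by grouped K-fold cross-validation with
    early stopping on held-out squared error.  Stage 2 runs a seeded
    derivative-free random search over depth, learning rate, subsampling,
    minimum child weight and L1/L2 regularization; the objective is the
    grouped-CV mean squared error.  The library defaults are always included
    as a candidate, so tuning can only improve its own objective.
    """
    cfg = config or ModelConfig()
    y = np.asarray(y, dtype=float)
    if len(y) < 20:
        raise ValueError("need at least 20 training rows")
    Xv = X.to_numpy(dtype=float)
    kf, groups = _grouped_folds(electrodes, cfg.tune_cv_folds)
    splits = list(kf.split(Xv, y, groups))

    # stage 1: number of trees via early stopping
    best_iters = []
    for tr, te in splits:
        m = _xgb({"n_estimators": cfg.stage1_max_trees,
                  "early_stopping_rounds": cfg.stage1_early_stopping}, seed)
        m.fit(Xv[tr], y[tr], eval_set=[(Xv[te], y[te])], verbose=False)
        best_iters.append(m.best_iteration + 1)
    n_trees = int(max(10, round(float(np.mean(best_iters)))))

    # stage 2: random search over the declared space
    rng = np.random.default_rng(seed)
    space = cfg.space

    def _sample() -> dict:
        lo, hi = space["learning_rate"]
        return {
            "max_depth": int(rng.integers(space["max_depth"][0],
                                          space["max_depth"][1] + 1)),
            "learning_rate": float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
            "subsample": float(rng.uniform(*space["subsample"])),
            "colsample_bytree": float(rng.uniform(*space["colsample_bytree"])),
            "min_child_weight": float(rng.uniform(*space["min_child_weight"])),
            "reg_alpha": float(rng.uniform(*space["reg_alpha"])),
            "reg_lambda": float(rng.uniform(*space["reg_lambda"])),
        }

    candidates = [{}] + [_sample() for _ in range(cfg.tune_evals)]

    def _cv_mse(params: dict) -> float:
        errs = []
        for tr, te in splits:
            m = _xgb({"n_estimators": n_trees, **params}, seed)
            m.fit(Xv[tr], y[tr], verbose=False)
            pred = m.predict(Xv[te])
            errs.append(float(np.mean((pred - y[te]) ** 2)))
        return float(np.mean(errs))

    scores = [_cv_mse(c) for c in candidates]
    best = candidates[int(np.argmin(scores))]
    return {"n_estimators": n_trees, **best}


def _electrode_labels(index: pd.MultiIndex) -> pd.Series:
    return pd.Series(
        [f"{p}:{s}" for p, s, _ in index], index=index, name="electrode"
    )


def loeo_predict(
    X: pd.DataFrame,
    y: pd.Series,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> tuple[pd.DataFrame, SelectionResult]:
    """Leave-one-electrode-out predictions with nested selection and tuning.

    ``X`` is indexed by (patient_id, side, contact_id); an electrode is one
    (patient_id, side).  For every electrode, consensus feature selection
    and hyperparameter tuning run on the remaining electrodes only, a model
    is fitted and the held-out contacts are predicted.  Returns the
    concatenated predictions and the per-fold selection result.
    """
    cfg = config or ModelConfig()
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    electrodes = _electrode_labels(X.index)
    unique = sorted(electrodes.unique())
    if len(unique) < 3:
        raise ValueError("need at least 3 electrodes for LOEO")

    fold_seeds = {
        e: int(s.generate_state(1)[0] % (2**31))
        for e, s in zip(unique, np.random.SeedSequence(seed).spawn(len(unique)))
    }

    rows = []
    per_fold: dict = {}
    params_per_fold: dict = {}
    for e in unique:
        test_mask = electrodes == e
        if not test_mask.any():
            warnings.warn(f"electrode {e} has no tested contacts; skipped",
                          stacklevel=2)
            continue
        tr = X.index[~test_mask]
        te = X.index[test_mask]
        fs = fold_seeds[e]
        selected = consensus_select(
            X.loc[tr], y.loc[tr], electrodes.loc[tr], seed=fs, config=cfg
        )
        params = tune_hyperparameters(
            X.loc[tr, selected], y.loc[tr], electrodes.loc[tr],
            seed=fs, config=cfg,
        )
        m = _xgb(params, fs)
        m.fit(X.loc[tr, selected].to_numpy(), y.loc[tr].to_numpy(),
              verbose=False)
        pred = m.predict(X.loc[te, selected].to_numpy())
        per_fold[e] = selected
        params_per_fold[e] = params
        for key, yt, yp in zip(te, y.loc[te], pred):
            rows.append(dict(
                patient_id=key[0], side=key[1], contact_id=key[2],
                y_true=float(yt), y_pred=float(yp), fold=e,
            ))
        log.info("fold %s: %d features, %d train rows",
                 e, len(selected), len(tr))

    freq = pd.Series(
        {c: np.mean([c in sel for sel in per_fold.values()])
         for c in X.columns},
        name="selection_frequency",
    )
    return pd.DataFrame(rows), SelectionResult(
        per_fold=per_fold, frequency=freq, params_per_fold=params_per_fold
    )


def train_full_and_apply(
    train_X: pd.DataFrame,
    train_y: pd.Series,
    new_X: pd.DataFrame,
    seed: int = 0,
    config: ModelConfig | None = None,
    training_cohort: str = "train",
) -> tuple[np.ndarray, ModelBundle]:
    """Fit once on the full training cohort and predict a new cohort.

    Consensus selection and tuning run on the entire training cohort;
    the new cohort's columns are aligned by name (missing columns raise,
    column order is irrelevant).
    """
    cfg = config or ModelConfig()
    train_y = pd.Series(np.asarray(train_y, dtype=float), index=train_X.index)
    electrodes = _electrode_labels(train_X.index)
    selected = consensus_select(
        train_X, train_y, electrodes, seed=seed, config=cfg
    )
    params = tune_hyperparameters(
        train_X[selected], train_y, electrodes, seed=seed, config=cfg
    )
    m = _xgb(params, seed)
    m.fit(train_X[selected].to_numpy(), train_y.to_numpy(), verbose=False)
    bundle = ModelBundle(
        model=m, hyperparameters=params, selected_features=selected,
        training_cohort=training_cohort, seed=seed,
    )
    return bundle.predict(new_X), bundle
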