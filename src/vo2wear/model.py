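"""Gradient-boosted VO2 regression and its evaluation harness.

``VO2Model`` is built from per-subject 1 Hz feature frames (the output of
:func:`vo2wear.features.build_feature_frame`). Its ``fit`` method trains a
boosted-tree regressor (XGBoost, squared-error objective) on the selected
feature set and returns a ``VO2Results`` object; ``loso`` runs
leave-one-subject-out cross-validation with a nested, subject-grouped
5-fold grid search per fold and returns ``CrossValidationResults`` carrying
per-subject and pooled MAE/R2, Bland-Altman agreement statistics, and
per-activity error tables.

Feature sets combine HR% (heart rate as % of age-predicted maximum),
RD = {respiration rate, breath amplitude difference}, MADs (motion
intensity) and SDI = {age, sex, BMI}; SDI is always included. The default
hyperparameter grid is the 8-cell product
{10, 50} trees x depth {1, 5} x learning rate {1, 0.1}.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "FEATURE_SETS",
    "HyperParams",
    "DEFAULT_GRID",
    "VO2Model",
    "VO2Results",
    "CrossValidationResults",
    "mae",
    "r2",
    "bland_altman",
    "BlandAltman",
    "compare_groups",
    "grid_search",
]

SDI_COLUMNS = ["age", "sex", "bmi"]

#: The seven admissible feature-set names and their resolved columns.
FEATURE_SETS: dict[str, list[str]] = {
    "HR%+SDI": ["hr_pct"] + SDI_COLUMNS,
    "RD+SDI": ["rr", "dapt"] + SDI_COLUMNS,
    "MADs+SDI": ["mads"] + SDI_COLUMNS,
    "HR%+RD+SDI": ["hr_pct", "rr", "dapt"] + SDI_COLUMNS,
    "HR%+MADs+SDI": ["hr_pct", "mads"] + SDI_COLUMNS,
    "RD+MADs+SDI": ["rr", "dapt", "mads"] + SDI_COLUMNS,
    "HR%+RD+MADs+SDI": ["hr_pct", "rr", "dapt", "mads"] + SDI_COLUMNS,
}

#: Coarse activity grouping for the per-activity error tables.
COARSE_ACTIVITY = {
    **{f"bruce_level_{k}": "treadmill" for k in range(1, 8)},
}


@dataclass(frozen=True, order=True)
class HyperParams:
    """Boosted-tree hyperparameters: tree count, depth, learning rate."""

    n_trees: int
    max_depth: int
    learning_rate: float

    def __post_init__(self) -> None:
        if self.n_trees <= 0 or self.max_depth <= 0 or not 0 < self.learning_rate <= 1:
            raise ValueError(f"invalid hyperparameters {self}")


DEFAULT_GRID: tuple[HyperParams, ...] = tuple(
    HyperParams(n, d, lr)
    for n, d, lr in itertools.product((10, 50), (1, 5), (1.0, 0.1))
)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def mae(true, pred) -> float:
    """Mean absolute error, ml/kg/min."""
    t = np.asarray(true, dtype=float)
    p = np.asarray(pred, dtype=float)
    if len(t) != len(p) or len(t) < 2:
        raise ValueError("inputs must have equal length >= 2")
    return float(np.mean(np.abs(t - p)))


def r2(true, pred) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    t = np.asarray(true, dtype=float)
    p = np.asarray(pred, dtype=float)
    if len(t) != len(p) or len(t) < 2:
        raise ValueError("inputs must have equal length >= 2")
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: zero-variance truth")
    return 1.0 - float(np.sum((t - p) ** 2)) / ss_tot


@dataclass(frozen=True)
class BlandAltman:
    """Agreement statistics of pred - true differences."""

    bias: float
    loa_low: float
    loa_high: float
    ci95_width: float
    sd: float


def bland_altman(true, pred) -> BlandAltman:
    """Bland-Altman agreement: bias and 1.96-sd limits of pred - true."""
    t = np.asarray(true, dtype=float)
    p = np.asarray(pred, dtype=float)
    if len(t) != len(p) or len(t) < 3:
        raise ValueError("inputs must have equal length >= 3")
    d = p - t
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        ci95_width=2 * 1.96 * sd,
        sd=sd,
    )


def compare_groups(groups: dict[str, np.ndarray], alpha: float = 0.05) -> dict:
    """Significance tests between metric groups.

    Two groups: two-sided independent-sample t-test. More: one-way ANOVA
    followed by Tukey HSD pairwise comparisons. Returns the p-values and
    which comparisons fall below ``alpha``.
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    out: dict = {"alpha": alpha}
    if len(arrays) == 2:
        stat, p = sstats.ttest_ind(arrays[0], arrays[1])
        out["test"] = "t-test"
        out["p"] = float(p)
        out["significant"] = bool(p < alpha)
    else:
        stat, p = sstats.f_oneway(*arrays)
        out["test"] = "anova+tukey"
        out["p"] = float(p)
        out["significant"] = bool(p < alpha)
        tk = sstats.tukey_hsd(*arrays)
        pairwise = {}
        for i, j in itertools.combinations(range(len(arrays)), 2):
            pairwise[(names[i], names[j])] = float(tk.pvalue[i, j])
        out["pairwise"] = pairwise
        out["significant_pairs"] = [k for k, v in pairwise.items() if v < alpha]
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _MeanPredictor:
    """Degenerate model returned for a constant training target."""

    def __init__(self, value: float) -> None:
        self.value = value

    def predict(self, X) -> np.ndarray:
        return np.full(np.asarray(X).shape[0], self.value)


def _stack_frames(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Long table: one row per (subject, second), SDI broadcast per row."""
    parts = []
    for f in frames:
        s = f.attrs.get("subject")
        if s is None:
            raise ValueError("feature frame lacks subject metadata")
        g = f.copy()
        g["subject_id"] = s.subject_id
        g["age"] = float(s.age)
        g["sex"] = float(s.sex_code)
        g["bmi"] = float(s.bmi)
        parts.append(g)
    return pd.concat(parts, ignore_index=True)


def _train_xgb(X: np.ndarray, y: np.ndarray, hp: HyperParams, seed: int):
    if np.ptp(y) == 0.0:
        warnings.warn("constant training target: returning mean predictor", stacklevel=2)
        return _MeanPredictor(float(y[0]))
    from xgboost import XGBRegressor

    model = XGBRegressor(
        n_estimators=hp.n_trees,
        max_depth=hp.max_depth,
        learning_rate=hp.learning_rate,
        objective="reg:squarederror",
        tree_method="hist",
        random_state=int(seed) % (2**31),
        n_jobs=1,
        verbosity=0,
    )
    model.fit(X, y)
    return model


def _subject_folds(subject_ids: np.ndarray, k: int) -> list[np.ndarray]:
    """Deterministic subject-grouped folds (subjects round-robin by order)."""
    subjects = list(dict.fromkeys(subject_ids))  # stable order
    if len(subjects) < k:
        warnings.warn(
            f"only {len(subjects)} subjects: reducing CV folds from {k}", stacklevel=2
        )
        k = len(subjects)
    assignment = {s: i % k for i, s in enumerate(subjects)}
    fold_of = np.array([assignment[s] for s in subject_ids])
    return [np.nonzero(fold_of == i)[0] for i in range(k)]


def grid_search(
    data: pd.DataFrame,
    columns: list[str],
    grid: tuple[HyperParams, ...] = DEFAULT_GRID,
    k: int = 5,
    seed: int = 0,
) -> tuple[HyperParams, pd.DataFrame]:
    """Pick the grid cell with the lowest mean subject-grouped k-fold CV MAE.

    Ties break deterministically toward fewer trees, then smaller depth,
    then larger learning rate. Returns (best cell, full CV table).
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    folds = _subject_folds(data["subject_id"].to_numpy(), k)
    X = data[columns].to_numpy(dtype=float)
    y = data["vo2"].to_numpy(dtype=float)
    rows = []
    for hp in grid:
        fold_maes = []
        for i, test_idx in enumerate(folds):
            train_mask = np.ones(len(data), dtype=bool)
            train_mask[test_idx] = False
            model = _train_xgb(X[train_mask], y[train_mask], hp, seed)
            fold_maes.append(mae(y[test_idx], model.predict(X[test_idx])))
        rows.append(
            {
                "n_trees": hp.n_trees,
                "max_depth": hp.max_depth,
                "learning_rate": hp.learning_rate,
                "cv_mae": float(np.mean(fold_maes)),
            }
        )
    table = pd.DataFrame(rows)
    order = sorted(
        range(len(grid)),
        key=lambda i: (
            round(table.loc[i, "cv_mae"], 12),
            grid[i].n_trees,
            grid[i].max_depth,
            -grid[i].learning_rate,
        ),
    )
    return grid[order[0]], table


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class VO2Model:
    """Instantaneous-VO2 regression over a cohort of feature frames.

    Parameters
    ----------
    frames : per-subject 1 Hz feature frames (``attrs["subject"]`` set),
        each with a ``vo2`` target column.
    feature_set : one of the seven admissible names (default the full
        "HR%+RD+MADs+SDI" combination).
    grid : hyperparameter candidates for the nested grid search.
    """

    def __init__(
        self,
        frames: list[pd.DataFrame],
        feature_set: str = "HR%+RD+MADs+SDI",
        grid: tuple[HyperParams, ...] = DEFAULT_GRID,
    ) -> None:
        if feature_set not in FEATURE_SETS:
            raise ValueError(
                f"unknown feature set {feature_set!r}; valid: {', '.join(FEATURE_SETS)}"
            )
        self.feature_set = feature_set
        self.columns = FEATURE_SETS[feature_set]
        self.grid = tuple(grid)
        self.data = _stack_frames(frames)
        if "vo2" not in self.data.columns or self.data["vo2"].isna().any():
            raise ValueError("all frames need a complete vo2 target column")
        counts = self.data.groupby("subject_id").size()
        short = counts[counts < 60].index.tolist()
        if short:
            warnings.warn(f"excluding subjects with < 60 rows: {short}", stacklevel=2)
            self.data = self.data[~self.data["subject_id"].isin(short)].reset_index(drop=True)
        self.subjects = list(dict.fromkeys(self.data["subject_id"]))

    @classmethod
    def from_frames(cls, frames, **kwargs) -> "VO2Model":
        return cls(frames, **kwargs)

    # -- single fit --------------------------------------------------------
    def fit(self, hyperparams: HyperParams | None = None, seed: int = 0) -> "VO2Results":
        """Train on every subject; grid-searches when no cell is given."""
        if len(self.data) < 100:
            raise ValueError("need >= 100 training rows")
        cv_table = None
        if hyperparams is None:
            hyperparams, cv_table = grid_search(self.data, self.columns, self.grid, seed=seed)
        X = self.data[self.columns].to_numpy(dtype=float)
        y = self.data["vo2"].to_numpy(dtype=float)
        booster = _train_xgb(X, y, hyperparams, seed)
        return VO2Results(self, booster, hyperparams, tuple(self.subjects), cv_table)

    # -- leave-one-subject-out --------------------------------------------
    def loso(self, seed: int = 0) -> "CrossValidationResults":
        """LOSO cross-validation with a nested grid search per fold."""
        if len(self.subjects) < 3:
            raise ValueError("LOSO needs >= 3 subjects")
        preds = []
        fold_info = []
        for held_out in self.subjects:
            train = self.data[self.data["subject_id"] != held_out]
            test = self.data[self.data["subject_id"] == held_out]
            train_subjects = set(train["subject_id"])
            assert held_out not in train_subjects, "LOSO leakage"
            hp, _ = grid_search(train, self.columns, self.grid, seed=seed)
            booster = _train_xgb(
                train[self.columns].to_numpy(dtype=float),
                train["vo2"].to_numpy(dtype=float),
                hp,
                seed,
            )
            yhat = booster.predict(test[self.columns].to_numpy(dtype=float))
            block = test[["subject_id", "t", "activity", "vo2"]].copy()
            block = block.rename(columns={"vo2": "true"})
            block["pred"] = np.asarray(yhat, dtype=float)
            preds.append(block)
            fold_info.append(
                {"held_out": held_out, "train_subjects": sorted(train_subjects), "params": hp}
            )
        return CrossValidationResults(
            predictions=pd.concat(preds, ignore_index=True),
            folds=fold_info,
            feature_set=self.feature_set,
            label="LOSO",
        )

    # -- sex-stratified crossover -----------------------------------------
    def gender_crossover(self, seed: int = 0) -> dict[str, "CrossValidationResults"]:
        """Within-sex LOSO plus train-on-one-sex / test-on-the-other.

        Returns four reports keyed "Male-Male", "Female-Female",
        "Male-Female", "Female-Male" (train-test order).
        """
        sex_of = self.data.groupby("subject_id")["sex"].first()
        males = [s for s in self.subjects if sex_of[s] == 1.0]
        females = [s for s in self.subjects if sex_of[s] == 0.0]
        if not males or not females:
            raise ValueError("gender crossover needs both sexes present")
        out: dict[str, CrossValidationResults] = {}
        for name, ids in (("Male-Male", males), ("Female-Female", females)):
            sub = self.data[self.data["subject_id"].isin(ids)]
            m = VO2Model.__new__(VO2Model)
            m.feature_set, m.columns, m.grid = self.feature_set, self.columns, self.grid
            m.data, m.subjects = sub.reset_index(drop=True), ids
            rep = m.loso(seed=seed)
            rep.label = name
            out[name] = rep
        for name, train_ids, test_ids in (
            ("Male-Female", males, females),
            ("Female-Male", females, males),
        ):
            train = self.data[self.data["subject_id"].isin(train_ids)]
            test = self.data[self.data["subject_id"].isin(test_ids)]
            assert not set(train["subject_id"]) & set(test["subject_id"])
            hp, _ = grid_search(train, self.columns, self.grid, seed=seed)
            booster = _train_xgb(
                train[self.columns].to_numpy(dtype=float),
                train["vo2"].to_numpy(dtype=float),
                hp,
                seed,
            )
            yhat = booster.predict(test[self.columns].to_numpy(dtype=float))
            block = test[["subject_id", "t", "activity", "vo2"]].copy()
            block = block.rename(columns={"vo2": "true"})
            block["pred"] = np.asarray(yhat, dtype=float)
            out[name] = CrossValidationResults(
                predictions=block.reset_index(drop=True),
                folds=[{"held_out": test_ids, "train_subjects": train_ids, "params": hp}],
                feature_set=self.feature_set,
                label=name,
            )
        return out


@dataclass
class VO2Results:
    """A trained boosted-tree VO2 regressor and its training context."""

    model: VO2Model
    booster: object
    hyperparams: HyperParams
    training_subjects: tuple[str, ...]
    cv_table: pd.DataFrame | None = None

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        """Predict 1 Hz VO2 (ml/kg/min) for a feature frame."""
        if set(self.model.columns) <= set(frame.columns):
            X = frame[self.model.columns].to_numpy(dtype=float)
        else:
            X = _stack_frames([frame])[self.model.columns].to_numpy(dtype=float)
        return np.asarray(self.booster.predict(X), dtype=float)

    def summary(self) -> str:
        y = self.model.data["vo2"].to_numpy()
        yhat = np.asarray(self.booster.predict(self.model.data[self.model.columns].to_numpy()))
        lines = [
            "VO2 boosted-tree regression",
            "=" * 42,
            f"feature set      : {self.model.feature_set}",
            f"columns          : {', '.join(self.model.columns)}",
            f"subjects         : {len(self.training_subjects)}",
            f"training rows    : {len(y)}",
            f"hyperparameters  : trees={self.hyperparams.n_trees}, "
            f"depth={self.hyperparams.max_depth}, lr={self.hyperparams.learning_rate:g}",
            f"training MAE     : {mae(y, yhat):.3f} ml/kg/min",
            f"training R^2     : {r2(y, yhat):.4f}",
        ]
        return "\n".join(lines)


@dataclass
class CrossValidationResults:
    """Held-out predictions and agreement statistics for one evaluation."""

    predictions: pd.DataFrame  # subject_id, t, activity, true, pred
    folds: list[dict]
    feature_set: str
    label: str = "LOSO"

    # -- per-subject and pooled metrics ------------------------------------
    def per_subject(self) -> pd.DataFrame:
        rows = []
        for sid, g in self.predictions.groupby("subject_id", sort=False):
            rows.append(
                {"subject_id": sid, "mae": mae(g["true"], g["pred"]), "r2": r2(g["true"], g["pred"])}
            )
        return pd.DataFrame(rows)

    def pooled(self) -> dict[str, float]:
        """Per-subject mean +- sd of MAE/R2 plus pooled-sample metrics."""
        per = self.per_subject()
        return {
            "mae_mean": float(per["mae"].mean()),
            "mae_sd": float(per["mae"].std(ddof=1)) if len(per) > 1 else 0.0,
            "r2_mean": float(per["r2"].mean()),
            "r2_sd": float(per["r2"].std(ddof=1)) if len(per) > 1 else 0.0,
            "mae_pooled": mae(self.predictions["true"], self.predictions["pred"]),
            "r2_pooled": r2(self.predictions["true"], self.predictions["pred"]),
            "n": int(len(self.predictions)),
        }

    def bland_altman(self) -> BlandAltman:
        return bland_altman(self.predictions["true"], self.predictions["pred"])

    def per_activity(self, coarse: bool = True) -> pd.Series:
        """MAE stratified by activity label ("unlabeled" seconds excluded)."""
        df = self.predictions[self.predictions["activity"] != "unlabeled"].copy()
        if coarse:
            df["activity"] = df["activity"].map(lambda a: COARSE_ACTIVITY.get(a, a))
        return df.groupby("activity").apply(
            lambda g: float(np.mean(np.abs(g["true"] - g["pred"]))), include_groups=False
        )

    def summary(self) -> str:
        p = self.pooled()
        ba = self.bland_altman()
        lines = [
            f"{self.label} cross-validation ({self.feature_set})",
            "=" * 50,
            f"subjects              : {self.predictions['subject_id'].nunique()}",
            f"held-out samples (n)  : {p['n']}",
            f"MAE  (subject mean+-sd): {p['mae_mean']:.2f} +- {p['mae_sd']:.2f} ml/kg/min",
            f"R^2  (subject mean+-sd): {p['r2_mean']:.3f} +- {p['r2_sd']:.3f}",
            f"MAE  (pooled)          : {p['mae_pooled']:.2f} ml/kg/min",
            f"R^2  (pooled)          : {p['r2_pooled']:.3f}",
            f"Bland-Altman bias      : {ba.bias:.3f} ml/kg/min",
            f"limits of agreement    : ({ba.loa_low:.2f}, {ba.loa_high:.2f})",
            f"CI95 width             : {ba.ci95_width:.2f} ml/kg/min",
            "",
            "per-activity MAE (ml/kg/min):",
        ]
        for act, v in self.per_activity().items():
            lines.append(f"  {act:<12s} {v:6.2f}")
        return "\n".join(lines)

    # -- plots -------------------------------------------------------------
    def plot_bland_altman(self, path=None):
        """Bland-Altman scatter with bias and limits of agreement."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        t = self.predictions["true"].to_numpy()
        pr = self.predictions["pred"].to_numpy()
        ba = self.bland_altman()
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot((t + pr) / 2, pr - t, ".", ms=1, alpha=0.3)
        for y, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
            ax.axhline(y, color="r", ls=style, lw=1)
        ax.set_xlabel("mean of estimate and reference (ml/kg/min)")
        ax.set_ylabel("estimate - reference (ml/kg/min)")
        ax.set_title(f"Bland-Altman, {self.label}")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig

    def plot_scatter(self, path=None):
        """Reference vs estimated VO2 scatter with the identity line."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        t = self.predictions["true"].to_numpy()
        pr = self.predictions["pred"].to_numpy()
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.plot(t, pr, ".", ms=1, alpha=0.3)
        lim = [min(t.min(), pr.min()), max(t.max(), pr.max())]
        ax.plot(lim, lim, "r-", lw=1)
        ax.set_xlabel("reference VO2 (ml/kg/min)")
        ax.set_ylabel("estimated VO2 (ml/kg/min)")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
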