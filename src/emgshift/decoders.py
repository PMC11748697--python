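"""Linear-discriminant decoding and the position-transfer experiments.

The shared engine is classic LDA: Gaussian classes with a pooled covariance
Sigma, discriminant

    delta_k(x) = x' Sigma^-1 mu_k - 1/2 mu_k' Sigma^-1 mu_k + log pi_k

with Sigma regularised as ``pooled_cov + ridge * I`` (64-dimensional Hudgins
features from a few thousand windows can be near-singular per class).

Three experiment scenarios are built on it, all split *by trial* so windows
of one trial never straddle the train/test boundary, and all z-scored with
statistics estimated on the training portion only:

* ``within_position``    — 6-grasp classification per position (5-fold CV),
* ``transfer_matrix``    — train on source position P_s, test on target P_t
  within one day's configuration, plus a one-versus-rest column pooling all
  remaining positions,
* ``position_per_grasp`` — 5-class position decoding for each grasp.

Per-participant numbers are fold means averaged over the participant's
sessions; scenario-level mean and sigma aggregate across participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .features import feature_columns
from .preprocess import zscore_apply, zscore_fit
from .protocol_sim import subseed


# ---------------------------------------------------------------------------
# LDA engine

@dataclass
class LinearDiscriminantModel:
    classes: np.ndarray          # sorted label values
    means: np.ndarray            # class x dim
    pooled_cov: np.ndarray       # dim x dim, symmetric PSD
    priors: np.ndarray           # empirical class frequencies, sums to 1
    ridge: float                 # diagonal regulariser added to pooled_cov

    def __post_init__(self) -> None:
        sigma = self.pooled_cov + self.ridge * np.eye(self.pooled_cov.shape[0])
        try:
            # precompute Sigma^-1 mu_k' via a Cholesky solve
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "regularised covariance is not positive definite; increase the "
                "ridge (e.g. ridge='auto') or supply more training windows"
            ) from err
        w = np.linalg.solve(chol.T, np.linalg.solve(chol, self.means.T))
        self._weights = w                                   # dim x class
        self._bias = (-0.5 * np.einsum("kd,dk->k", self.means, w)
                      + np.log(self.priors))

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def fit_lda(X: np.ndarray, y: np.ndarray, ridge: float | str = "auto"
            ) -> LinearDiscriminantModel:
    """Fit the pooled-covariance linear discriminant.

    ``ridge='auto'`` uses 1e-6 * trace(Sigma)/dim; ``ridge=0`` raises on a
    singular pooled covariance with a remediation hint.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be samples x dim aligned with y")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to fit a discriminant")
    if np.any(counts < 2):
        bad = classes[counts < 2].tolist()
        raise ValueError(f"classes {bad} have fewer than 2 samples")
    n, dim = X.shape
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    scatter = np.zeros((dim, dim))
    for c, mu in zip(classes, means):
        d = X[y == c] - mu
        scatter += d.T @ d
    pooled = scatter / (n - classes.size)
    pooled = (pooled + pooled.T) / 2.0
    if ridge == "auto":
        ridge_val = 1e-6 * np.trace(pooled) / dim
    else:
        ridge_val = float(ridge)
        if ridge_val < 0:
            raise ValueError("ridge must be non-negative")
    return LinearDiscriminantModel(classes=classes, means=means, pooled_cov=pooled,
                                   priors=counts / n, ridge=ridge_val)


def predict_scores(model: LinearDiscriminantModel, X: np.ndarray) -> np.ndarray:
    """Discriminant scores delta_k(x), samples x classes."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {X.shape[1]}")
    return X @ model._weights + model._bias


def predict(model: LinearDiscriminantModel, X: np.ndarray) -> np.ndarray:
    """Argmax of the discriminants; ties resolve to the lowest class label."""
    scores = predict_scores(model, X)
    return model.classes[np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# Trial-wise cross-validation

def trial_cv_split(trial_ids: np.ndarray, strata: np.ndarray, n_folds: int = 5,
                   seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified K-fold partition of *trials* (not windows).

    Returns ``[(train_ids, test_ids), ...]``; every trial appears in exactly
    one test fold, so each fold is a 1/n_folds held-out share (20% at the
    default 5 folds).  Stratification keeps label proportions per fold.
    """
    trial_ids = np.asarray(trial_ids)
    strata = np.asarray(strata)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if trial_ids.shape[0] != strata.shape[0]:
        raise ValueError("trial_ids and strata must align")
    if np.unique(trial_ids).size != trial_ids.size:
        raise ValueError("trial ids must be unique")
    _, counts = np.unique(strata, return_counts=True)
    if np.any(counts < n_folds):
        raise ValueError(
            f"every stratum needs >= {n_folds} trials; smallest has {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    return [(trial_ids[tr], trial_ids[te]) for tr, te in skf.split(trial_ids, strata)]


# ---------------------------------------------------------------------------
# Experiment plumbing

@dataclass
class ExperimentResult:
    """Accuracies of one scenario: per participant, plus mean and sigma."""

    scenario: str
    per_subject: dict[int, float]
    extras: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.per_subject.values())))

    @property
    def sd(self) -> float:
        return float(np.std(list(self.per_subject.values())))


def _feature_cols(df: pd.DataFrame) -> list[str]:
    n_ch = sum(c.endswith("_mav") for c in df.columns)
    cols = feature_columns(n_ch)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing[:4]}...")
    return cols


def _trial_table(df: pd.DataFrame, label_col: str) -> tuple[np.ndarray, np.ndarray]:
    tab = df[["trial_id", label_col]].drop_duplicates()
    if tab["trial_id"].duplicated().any():
        raise ValueError("a trial maps to multiple labels; trial ids must be unique")
    tab = tab.sort_values("trial_id")  # row-order invariance of the CV split
    return tab["trial_id"].to_numpy(), tab[label_col].to_numpy()


def _fit_fold(train: pd.DataFrame, label_col: str, cols: list[str],
              ridge: float | str):
    stats = zscore_fit(train[cols].to_numpy())
    model = fit_lda(zscore_apply(train[cols].to_numpy(), stats),
                    train[label_col].to_numpy(), ridge)
    return stats, model


def _count_correct(model, stats, test: pd.DataFrame, label_col: str,
                   cols: list[str]) -> tuple[int, int]:
    pred = predict(model, zscore_apply(test[cols].to_numpy(), stats))
    return int((pred == test[label_col].to_numpy()).sum()), len(test)


def _session_groups(df: pd.DataFrame):
    for (participant, day, session), sdf in df.groupby(["participant", "day", "session"]):
        yield int(participant), int(day), int(session), sdf


# ---------------------------------------------------------------------------
# Scenarios

def within_position(features: pd.DataFrame, position: int, *, n_folds: int = 5,
                    seed: int = 0, ridge: float | str = "auto",
                    label_col: str = "grasp") -> ExperimentResult:
    """Grasp classification with train and test data from one position."""
    sub = features[features["position"] == position]
    if sub.empty:
        raise ValueError(f"no windows recorded at position {position}")
    cols = _feature_cols(sub)
    session_rows = []
    for participant, day, session, sdf in _session_groups(sub):
        ids, strata = _trial_table(sdf, label_col)
        if np.unique(strata).size < 2:
            raise ValueError(
                f"participant {participant} day {day} session {session}: "
                "only one class present at this position"
            )
        folds = trial_cv_split(ids, strata, n_folds,
                               subseed(seed, participant, day, session, position))
        accs = []
        for train_ids, test_ids in folds:
            stats, model = _fit_fold(sdf[sdf.trial_id.isin(train_ids)], label_col,
                                     cols, ridge)
            nc, nt = _count_correct(model, stats, sdf[sdf.trial_id.isin(test_ids)],
                                    label_col, cols)
            accs.append(nc / nt)
        session_rows.append((participant, day, session, float(np.mean(accs))))
    by_subject: dict[int, list[float]] = {}
    for participant, day, session, acc in session_rows:
        by_subject.setdefault(participant, []).append(acc)
    per_subject = {p: float(np.mean(v)) for p, v in by_subject.items()}
    return ExperimentResult(
        scenario="within_position", per_subject=per_subject,
        extras={"position": position,
                "per_session": pd.DataFrame(session_rows,
                                            columns=["participant", "day", "session",
                                                     "accuracy"])})


def transfer_matrix(features: pd.DataFrame, day: int, *, n_folds: int = 5,
                    seed: int = 0, ridge: float | str = "auto") -> ExperimentResult:
    """Source -> target position transfer within one day's configuration.

    Cell (s, t): the model is fitted on P_s's training trials of a fold and
    tested on P_t's held-out trials of the same fold, so the diagonal
    reproduces the within-position protocol on identical folds.  The OVR
    column pools every off-diagonal test window of its row (micro average).
    """
    sub = features[features["day"] == day]
    if sub.empty:
        raise ValueError(f"no windows recorded on day {day}")
    positions = sorted(sub["position"].unique())
    if len(positions) < 2:
        raise ValueError(f"day {day} holds fewer than 2 positions")
    cols = _feature_cols(sub)

    correct: dict[int, np.ndarray] = {}
    total: dict[int, np.ndarray] = {}
    npos = len(positions)
    for participant, d, session, sdf in _session_groups(sub):
        pos_dfs = {p: sdf[sdf.position == p] for p in positions}
        folds = {}
        for p in positions:
            ids, strata = _trial_table(pos_dfs[p], "grasp")
            folds[p] = trial_cv_split(ids, strata, n_folds,
                                      subseed(seed, participant, d, session, p))
        c = correct.setdefault(participant, np.zeros((npos, npos), dtype=int))
        t = total.setdefault(participant, np.zeros((npos, npos), dtype=int))
        for k in range(n_folds):
            for i, s in enumerate(positions):
                train = pos_dfs[s][pos_dfs[s].trial_id.isin(folds[s][k][0])]
                stats, model = _fit_fold(train, "grasp", cols, ridge)
                for j, tgt in enumerate(positions):
                    test = pos_dfs[tgt][pos_dfs[tgt].trial_id.isin(folds[tgt][k][1])]
                    nc, nt = _count_correct(model, stats, test, "grasp", cols)
                    c[i, j] += nc
                    t[i, j] += nt

    subjects = sorted(correct)
    matrices = {p: correct[p] / total[p] for p in subjects}
    mean_matrix = np.mean([matrices[p] for p in subjects], axis=0)
    sd_matrix = np.std([matrices[p] for p in subjects], axis=0)
    off = ~np.eye(npos, dtype=bool)
    ovr = {}
    for p in subjects:
        ovr[p] = correct[p][off].reshape(npos, npos - 1).sum(axis=1) \
            / total[p][off].reshape(npos, npos - 1).sum(axis=1)
    ovr_mean = np.mean([ovr[p] for p in subjects], axis=0)

    per_subject = {p: float(np.mean(np.diag(matrices[p]))) for p in subjects}
    labels = [f"P{p}" for p in positions]
    return ExperimentResult(
        scenario="transfer_matrix", per_subject=per_subject,
        extras={
            "day": day,
            "positions": positions,
            "matrix": pd.DataFrame(mean_matrix, index=labels, columns=labels),
            "matrix_sd": pd.DataFrame(sd_matrix, index=labels, columns=labels),
            "ovr": pd.Series(ovr_mean, index=labels, name="OVR"),
            "per_subject_matrix": matrices,
            "per_subject_counts": {p: (correct[p], total[p]) for p in subjects},
            "diag_mean": float(np.mean(np.diag(mean_matrix))),
            "offdiag_mean": float(np.mean(mean_matrix[off])),
        })


def position_per_grasp(features: pd.DataFrame, day: int, *, n_folds: int = 5,
                       seed: int = 0, ridge: float | str = "auto") -> ExperimentResult:
    """Position decoding for each grasp within one day's configuration."""
    sub = features[features["day"] == day]
    if sub.empty:
        raise ValueError(f"no windows recorded on day {day}")
    cols = _feature_cols(sub)
    grasps = sorted(sub["grasp"].unique())
    per_grasp_subject: dict[int, dict[int, float]] = {g: {} for g in grasps}
    for g in grasps:
        gdf = sub[sub["grasp"] == g]
        if gdf.empty:
            raise ValueError(f"grasp {g} missing from day {day}")
        acc_by_subject: dict[int, list[float]] = {}
        for participant, d, session, sdf in _session_groups(gdf):
            ids, strata = _trial_table(sdf, "position")
            folds = trial_cv_split(ids, strata, n_folds,
                                   subseed(seed, participant, d, session, 100 + g))
            accs = []
            for train_ids, test_ids in folds:
                stats, model = _fit_fold(sdf[sdf.trial_id.isin(train_ids)],
                                         "position", cols, ridge)
                nc, nt = _count_correct(model, stats,
                                        sdf[sdf.trial_id.isin(test_ids)],
                                        "position", cols)
                accs.append(nc / nt)
            acc_by_subject.setdefault(participant, []).append(float(np.mean(accs)))
        per_grasp_subject[g] = {p: float(np.mean(v)) for p, v in acc_by_subject.items()}

    table = pd.Series({g: float(np.mean(list(v.values())))
                       for g, v in per_grasp_subject.items()}, name="accuracy")
    subjects = sorted({p for v in per_grasp_subject.values() for p in v})
    per_subject = {p: float(np.mean([per_grasp_subject[g][p] for g in grasps]))
                   for p in subjects}
    return ExperimentResult(
        scenario="position_per_grasp", per_subject=per_subject,
        extras={"day": day, "table": table, "per_grasp_subject": per_grasp_subject})
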