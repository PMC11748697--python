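"""Hierarchical multi-label classification of (position, grasp).

A two-level tree: a position encoder E_p (parent node) predicts the arm
position z' from the Hudgins vector x, then the sample is routed to the
grasp encoder E_g:z' attached to that position, which predicts the grasp y'
from the augmented vector x (+) norm(z').  The hierarchy constraint holds by
construction — a grasp prediction is always produced by the encoder of its
predicted parent — and is still audited at predict time.

Training merges data from all nine positions across both day configurations
(position 5, shared by both, is taken from only one of them), splits by
trial exactly like the flat experiments, fits E_p on (x, z), and fits each
E_g:n on the ground-truth-z = n samples augmented with norm(n).

Two metrics are reported over the same predictions:

* strict accuracy — fraction with y' = y AND z' = z (the multi-label pair
  must be fully correct), and
* soft accuracy  — the position condition is frozen and only y' = y counts.

Logically strict <= min(soft, E_p accuracy) on any prediction set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decoders import LinearDiscriminantModel, fit_lda, predict, trial_cv_split
from .features import feature_columns
from .preprocess import zscore_apply, zscore_fit
from .protocol_sim import subseed

N_POSITIONS = 9


def z_norm(position: np.ndarray | int, mode: str = "scalar") -> np.ndarray:
    """Normalised position context appended to the feature vector.

    ``scalar`` maps label z in 1..9 to (z-1)/8 in [0, 1] (one extra column);
    ``onehot`` appends a 9-column indicator.
    """
    z = np.atleast_1d(np.asarray(position, dtype=np.int64))
    if np.any((z < 1) | (z > N_POSITIONS)):
        raise ValueError("position labels must lie in 1-9")
    if mode == "scalar":
        return ((z - 1) / (N_POSITIONS - 1))[:, None]
    if mode == "onehot":
        return np.eye(N_POSITIONS)[z - 1]
    raise ValueError(f"unknown z_norm mode {mode!r}")


def augment(X: np.ndarray, position: np.ndarray | int, mode: str = "scalar") -> np.ndarray:
    """Concatenate x with the normalised position context, x (+) norm(z)."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    ctx = z_norm(position, mode)
    if ctx.shape[0] == 1 and X.shape[0] > 1:
        ctx = np.repeat(ctx, X.shape[0], axis=0)
    if ctx.shape[0] != X.shape[0]:
        raise ValueError("position context does not align with X")
    return np.hstack([X, ctx])


@dataclass
class HMCModel:
    """Position encoder plus one routed grasp encoder per position."""

    position_encoder: LinearDiscriminantModel
    grasp_encoders: dict[int, LinearDiscriminantModel]
    z_norm_mode: str = "scalar"
    position5_source: str = "+"

    def __post_init__(self) -> None:
        for n, enc in self.grasp_encoders.items():
            expect = self.position_encoder.n_features \
                + (1 if self.z_norm_mode == "scalar" else N_POSITIONS)
            if enc.n_features != expect:
                raise ValueError(
                    f"grasp encoder {n} expects {enc.n_features} features, "
                    f"augmentation yields {expect}"
                )


@dataclass
class HMCPredictions:
    """Multi-label predictions with ground truth and the routing audit trail."""

    y_pred: np.ndarray
    z_pred: np.ndarray
    y_true: np.ndarray
    z_true: np.ndarray
    routes: np.ndarray  # encoder id that produced each y_pred

    def routing_violations(self) -> int:
        """Predictions whose grasp did not come from the encoder of z'."""
        return int(np.count_nonzero(self.routes != self.z_pred))


def assemble_hmc_dataset(features: pd.DataFrame,
                         position5_source: str = "+") -> pd.DataFrame:
    """Merge both day configurations into one 9-position dataset.

    Position 5 appears in both configurations; only the trials of
    ``position5_source`` ('+' = day 1, 'x' = day 2) are kept so every
    position contributes a single day's trials.
    """
    if position5_source not in ("+", "x"):
        raise ValueError("position5_source must be '+' or 'x'")
    days = set(features["day"].unique())
    if not {1, 2} <= days:
        raise ValueError("both day configurations are required for the merge")
    drop_day = 2 if position5_source == "+" else 1
    merged = features[~((features["position"] == 5) & (features["day"] == drop_day))]
    present = set(merged["position"].unique())
    missing = set(range(1, N_POSITIONS + 1)) - present
    if missing:
        raise ValueError(f"positions {sorted(missing)} absent from the merge")
    return merged


def train_hmc(X: np.ndarray, y: np.ndarray, z: np.ndarray, *,
              ridge: float | str = "auto", z_norm_mode: str = "scalar",
              position5_source: str = "+") -> HMCModel:
    """Fit E_p on (x, z) and each E_g:n on the ground-truth z = n group."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    z = np.asarray(z)
    zvals = np.unique(z)
    if set(zvals) != set(range(1, N_POSITIONS + 1)):
        raise ValueError(f"training data must cover positions 1-9, got {zvals.tolist()}")
    position_encoder = fit_lda(X, z, ridge)
    grasp_encoders = {}
    for n in range(1, N_POSITIONS + 1):
        mask = z == n
        if np.unique(y[mask]).size < 2:
            raise ValueError(f"position {n} lacks a second grasp class")
        grasp_encoders[n] = fit_lda(augment(X[mask], n, z_norm_mode), y[mask], ridge)
    return HMCModel(position_encoder, grasp_encoders, z_norm_mode, position5_source)


def predict_hmc(model: HMCModel, X: np.ndarray, y_true: np.ndarray,
                z_true: np.ndarray, oracle_routing: bool = False) -> HMCPredictions:
    """Route each sample through E_p then the grasp encoder of z'.

    ``oracle_routing=True`` routes by the true position instead (a
    diagnostic upper bound on routing damage); the default follows the
    predicted parent, as the hierarchy demands.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    z_pred = predict(model.position_encoder, X)
    route_by = np.asarray(z_true) if oracle_routing else z_pred
    y_pred = np.empty(X.shape[0], dtype=np.asarray(y_true).dtype)
    routes = np.empty(X.shape[0], dtype=np.int64)
    for n in np.unique(route_by):
        mask = route_by == n
        enc = model.grasp_encoders[int(n)]
        y_pred[mask] = predict(enc, augment(X[mask], int(n), model.z_norm_mode))
        routes[mask] = int(n)
    return HMCPredictions(y_pred=y_pred, z_pred=z_pred,
                          y_true=np.asarray(y_true), z_true=np.asarray(z_true),
                          routes=routes)


def strict_accuracy(pred: HMCPredictions) -> float:
    """Fraction of samples with both labels correct (y' = y and z' = z)."""
    if pred.y_pred.size == 0:
        raise ValueError("empty prediction set")
    return float(np.mean((pred.y_pred == pred.y_true) & (pred.z_pred == pred.z_true)))


def soft_accuracy(pred: HMCPredictions) -> float:
    """Grasp-only accuracy of the same predictions (position frozen)."""
    if pred.y_pred.size == 0:
        raise ValueError("empty prediction set")
    return float(np.mean(pred.y_pred == pred.y_true))


def position_accuracy(pred: HMCPredictions) -> float:
    """Accuracy of the parent position encoder alone."""
    if pred.z_pred.size == 0:
        raise ValueError("empty prediction set")
    return float(np.mean(pred.z_pred == pred.z_true))


@dataclass
class HMCReport:
    """Cross-validated hierarchy results aggregated across participants."""

    strict: pd.DataFrame            # per true position: mean, sd across subjects
    soft: pd.DataFrame
    ep_mean: float                  # position-encoder accuracy
    ep_sd: float
    overall_strict: float
    overall_soft: float
    per_subject: pd.DataFrame       # participant x (strict, soft, ep)
    routing_violations: int = 0
    extras: dict = field(default_factory=dict)


def hmc_report(features: pd.DataFrame, *, n_folds: int = 5, seed: int = 0,
               ridge: float | str = "auto", position5_source: str = "+",
               z_norm_mode: str = "scalar", oracle_routing: bool = False) -> HMCReport:
    """Run the full hierarchy experiment on a two-day feature table.

    Day-1 and day-2 recordings of the same session index are merged into one
    9-position dataset per participant, split 5-fold by trial (stratified on
    the joint (grasp, position) label), and evaluated with the strict and
    soft metrics per true position.
    """
    merged = assemble_hmc_dataset(features, position5_source)
    n_ch = sum(c.endswith("_mav") for c in merged.columns)
    cols = feature_columns(n_ch)

    positions = list(range(1, N_POSITIONS + 1))
    per_subject_rows = []
    strict_by_subject: dict[int, pd.Series] = {}
    soft_by_subject: dict[int, pd.Series] = {}
    violations = 0
    for participant, pdf in merged.groupby("participant"):
        strict_c = np.zeros(N_POSITIONS)
        strict_n = np.zeros(N_POSITIONS)
        soft_c = np.zeros(N_POSITIONS)
        ep_c = 0
        ep_n = 0
        for session, sdf in pdf.groupby("session"):
            sdf = sdf.assign(trial_key=sdf["day"] * 1000 + sdf["trial_id"])
            tab = sdf[["trial_key", "grasp", "position"]].drop_duplicates()
            strata = tab["grasp"].to_numpy() * 10 + tab["position"].to_numpy()
            folds = trial_cv_split(tab["trial_key"].to_numpy(), strata, n_folds,
                                   subseed(seed, 900, int(participant), int(session)))
            for train_keys, test_keys in folds:
                train = sdf[sdf.trial_key.isin(train_keys)]
                test = sdf[sdf.trial_key.isin(test_keys)]
                stats = zscore_fit(train[cols].to_numpy())
                model = train_hmc(zscore_apply(train[cols].to_numpy(), stats),
                                  train["grasp"].to_numpy(),
                                  train["position"].to_numpy(),
                                  ridge=ridge, z_norm_mode=z_norm_mode,
                                  position5_source=position5_source)
                pred = predict_hmc(model, zscore_apply(test[cols].to_numpy(), stats),
                                   test["grasp"].to_numpy(),
                                   test["position"].to_numpy(),
                                   oracle_routing=oracle_routing)
                violations += pred.routing_violations()
                ep_c += int(np.sum(pred.z_pred == pred.z_true))
                ep_n += pred.z_true.size
                for i, p in enumerate(positions):
                    mask = pred.z_true == p
                    strict_n[i] += int(mask.sum())
                    strict_c[i] += int(np.sum(mask & (pred.y_pred == pred.y_true)
                                              & (pred.z_pred == pred.z_true)))
                    soft_c[i] += int(np.sum(mask & (pred.y_pred == pred.y_true)))
        with np.errstate(invalid="ignore"):
            strict_by_subject[int(participant)] = pd.Series(strict_c / strict_n,
                                                            index=positions)
            soft_by_subject[int(participant)] = pd.Series(soft_c / strict_n,
                                                          index=positions)
        per_subject_rows.append((int(participant),
                                 float(strict_c.sum() / strict_n.sum()),
                                 float(soft_c.sum() / strict_n.sum()),
                                 float(ep_c / ep_n)))

    subjects = sorted(strict_by_subject)
    strict_tab = pd.DataFrame({
        "mean": pd.concat(strict_by_subject, axis=1)[subjects].mean(axis=1),
        "sd": pd.concat(strict_by_subject, axis=1)[subjects].std(axis=1, ddof=0),
    })
    soft_tab = pd.DataFrame({
        "mean": pd.concat(soft_by_subject, axis=1)[subjects].mean(axis=1),
        "sd": pd.concat(soft_by_subject, axis=1)[subjects].std(axis=1, ddof=0),
    })
    per_subject = pd.DataFrame(per_subject_rows,
                               columns=["participant", "strict", "soft", "ep"]
                               ).set_index("participant")
    return HMCReport(
        strict=strict_tab, soft=soft_tab,
        ep_mean=float(per_subject["ep"].mean()), ep_sd=float(per_subject["ep"].std(ddof=0)),
        overall_strict=float(per_subject["strict"].mean()),
        overall_soft=float(per_subject["soft"].mean()),
        per_subject=per_subject, routing_violations=violations,
        extras={"position5_source": position5_source, "n_folds": n_folds})
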