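"""PCA -> (optional TIV residualisation) -> RBF-SVM sex classification.

The engine mirrors a common structural-neuroimaging pipeline: principal
component analysis for dimensionality reduction, an RBF-kernel support vector
machine tuned over log-uniform (C, gamma) with an inner stratified CV loop,
and a Platt-style sigmoid calibration of the decision scores.

Featurewise confound removal operates on the PCA component scores: every
component is residualised against TIV with ordinary least squares whose
coefficients are learnt on training data only and re-used, never refit, on
test data — the "CV-consistent" discipline that prevents confound-removal
leakage.  Within every tuning fold the decomposition and the remover are
refit on that fold's training half.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.exceptions import ConvergenceWarning
import pandas as pd
from scipy.special import expit
from sklearn.decomposition import PCA
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .config import HyperparameterSpace

__all__ = [
    "DecompositionModel",
    "ConfoundRemover",
    "PipelineModel",
    "fit_decomposition",
    "fit_confound_remover",
    "apply_confound_remover",
    "tune_and_train",
    "cross_validate",
    "assess_calibration",
    "predict",
    "save_model",
    "load_model",
]

SCHEMA_VERSION = 1

# libsvm can spend minutes failing to converge for hopeless (C, gamma)
# candidates on signal-free data; the cap bounds the cost of one candidate
# without affecting converged fits
_SVC_MAX_ITER = 200_000


def _make_svc(C: float, gamma: float) -> SVC:
    return SVC(kernel="rbf", C=C, gamma=gamma, max_iter=_SVC_MAX_ITER)


def _fit_svc(svc: SVC, Z: np.ndarray, y: np.ndarray) -> SVC:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svc.fit(Z, y)
    return svc


# --------------------------------------------------------------------------
# decomposition

@dataclass
class DecompositionModel:
    """Mean-centering offsets plus orthonormal PCA loadings."""

    mean: np.ndarray          # (n_features,)
    loadings: np.ndarray      # (n_components, n_features), rows orthonormal
    n_components: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.shape[1] != self.mean.shape[0]:
            raise ValueError(
                f"feature dimension {X.shape[1]} != fitted {self.mean.shape[0]}"
            )
        return (X - self.mean) @ self.loadings.T

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, float) @ self.loadings + self.mean


def fit_decomposition(X: np.ndarray) -> DecompositionModel:
    """Fit mean-centred PCA retaining ``min(n_subjects, n_features)`` components.

    After centering at most ``n_subjects - 1`` components carry nonzero
    variance; the full count is retained so the transform is lossless at full
    rank.  Raises on a constant feature matrix.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if np.allclose(X, X[0], atol=0.0):
        raise ValueError("constant feature matrix has no principal components")
    k = min(n, p)
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(X)
    return DecompositionModel(mean=pca.mean_, loadings=pca.components_, n_components=k)


# --------------------------------------------------------------------------
# confound removal

@dataclass
class ConfoundRemover:
    """Per-component OLS fit of component score on TIV (intercept + slope).

    Coefficients are learnt once, on the training partition; ``apply`` only
    ever subtracts stored fitted values.  ``n_fit`` records the training size
    as a leakage audit trail.
    """

    intercepts: np.ndarray  # (n_components,)
    slopes: np.ndarray      # (n_components,)
    n_fit: int
    tiv_min: float = -np.inf
    tiv_max: float = np.inf
    clip_extrapolation: bool = True

    def fitted_values(self, tiv: np.ndarray) -> np.ndarray:
        tiv = np.asarray(tiv, float)
        if self.clip_extrapolation:
            # a linear confound fit is only trusted on the TIV support it was
            # learnt on; beyond it the fitted values are held constant
            tiv = np.clip(tiv, self.tiv_min, self.tiv_max)
        return self.intercepts[None, :] + np.outer(tiv, self.slopes)


def fit_confound_remover(components: np.ndarray, tiv: np.ndarray) -> ConfoundRemover:
    Z = np.asarray(components, float)
    tiv = np.asarray(tiv, float)
    if Z.shape[0] != tiv.shape[0]:
        raise ValueError("components and TIV are not aligned")
    if np.ptp(tiv) == 0.0:
        raise ValueError(
            "TIV is constant; confound removal is undefined — disable removal"
        )
    design = np.column_stack([np.ones_like(tiv), tiv])
    coef, *_ = np.linalg.lstsq(design, Z, rcond=None)
    return ConfoundRemover(
        intercepts=coef[0], slopes=coef[1], n_fit=len(tiv),
        tiv_min=float(tiv.min()), tiv_max=float(tiv.max()),
    )


def apply_confound_remover(
    remover: ConfoundRemover, components: np.ndarray, tiv: np.ndarray
) -> np.ndarray:
    """Subtract the stored fitted values; never refits."""
    Z = np.asarray(components, float)
    tiv = np.asarray(tiv, float)
    if Z.shape[1] != remover.slopes.shape[0]:
        raise ValueError("component dimension mismatch with fitted remover")
    if Z.shape[0] != tiv.shape[0]:
        raise ValueError("components and TIV are not aligned")
    return Z - remover.fitted_values(tiv)


# --------------------------------------------------------------------------
# model container

@dataclass
class PipelineModel:
    """A fully fitted classification pipeline.

    Label convention: the positive class is "male"; ``prob_male`` is the
    calibrated probability of the male class and the predicted label is male
    iff ``prob_male >= 0.5`` (ties label male).
    """

    decomposition: DecompositionModel
    remover: ConfoundRemover | None
    svc: SVC
    calib_slope: float
    calib_intercept: float
    C: float
    gamma: float
    inner_cv_score: float
    n_train: int
    n_features: int
    use_confound_removal: bool
    calib_iso: object | None = None  # fitted isotonic map, if chosen
    meta: dict = field(default_factory=dict)

    def _scores(self, X: np.ndarray, tiv: np.ndarray | None) -> np.ndarray:
        Z = self.decomposition.transform(np.asarray(X, float))
        if self.remover is not None:
            if tiv is None:
                raise ValueError("model uses confound removal; TIV is required")
            Z = apply_confound_remover(self.remover, Z, tiv)
        return self.svc.decision_function(Z)

    def predict_proba_male(self, X: np.ndarray, tiv: np.ndarray | None = None) -> np.ndarray:
        s = self._scores(X, tiv)
        if self.calib_iso is not None:
            return np.asarray(self.calib_iso.predict(s), float)
        return expit(self.calib_slope * s + self.calib_intercept)


def _encode(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind == "O":
        y = y.astype(str)
    if y.dtype.kind in "US":
        bad = set(np.unique(y)) - {"F", "M"}
        if bad:
            raise ValueError(f"labels must be F/M, found {sorted(bad)}")
        return (y == "M").astype(int)
    return y.astype(int)


def _fit_stage(X, tiv, use_cr):
    dec = fit_decomposition(X)
    Z = dec.transform(X)
    remover = None
    if use_cr:
        remover = fit_confound_remover(Z, tiv)
        Z = apply_confound_remover(remover, Z, tiv)
    return dec, remover, Z


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size: int) -> np.ndarray:
    if lo == hi:
        return np.full(size, lo)
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def tune_and_train(
    train_features: np.ndarray,
    train_labels,
    train_tiv: np.ndarray | None,
    space: HyperparameterSpace,
    use_confound_removal: bool = False,
    seed: int = 0,
    calibration: str = "sigmoid",
) -> PipelineModel:
    """Seeded random search over log-uniform (C, gamma), then refit and calibrate.

    Candidates are scored by inner stratified-CV balanced accuracy with the
    decomposition (and, when enabled, the confound remover) refit inside every
    fold on that fold's training half.  The winning pair is refit on the full
    training sample; a calibration map — sigmoid (Platt, default) or isotonic —
    is then learnt from out-of-fold decision scores obtained by refitting the
    whole pipeline per calibration fold.
    """
    if calibration not in ("sigmoid", "isotonic"):
        raise ValueError("calibration must be 'sigmoid' or 'isotonic'")
    X = np.asarray(train_features, float)
    y = _encode(train_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if use_confound_removal and train_tiv is None:
        raise ValueError("confound removal requested but no TIV given")
    tiv = None if train_tiv is None else np.asarray(train_tiv, float)

    ss = np.random.SeedSequence(seed)
    s_search, s_inner, s_calib = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    rng = np.random.default_rng(s_search)
    Cs = _loguniform(rng, *space.C_range, space.n_search_iters)
    gammas = _loguniform(rng, *space.gamma_range, space.n_search_iters)

    inner = StratifiedKFold(space.inner_folds, shuffle=True, random_state=s_inner)
    # transform each fold once; candidate loop only refits the SVM
    folds = []
    for tr, te in inner.split(X, y):
        dec, rem, Ztr = _fit_stage(X[tr], None if tiv is None else tiv[tr], use_confound_removal)
        Zte = dec.transform(X[te])
        if rem is not None:
            Zte = apply_confound_remover(rem, Zte, tiv[te])
        folds.append((Ztr, y[tr], Zte, y[te]))

    mean_scores = np.empty(space.n_search_iters)
    for i, (C, gamma) in enumerate(zip(Cs, gammas)):
        accs = []
        for Ztr, ytr, Zte, yte in folds:
            svc = _fit_svc(_make_svc(C, gamma), Ztr, ytr)
            accs.append(balanced_accuracy_score(yte, svc.predict(Zte)))
        mean_scores[i] = float(np.mean(accs))
    best = int(np.argmax(mean_scores))
    C_best, gamma_best = float(Cs[best]), float(gammas[best])

    dec, rem, Z = _fit_stage(X, tiv, use_confound_removal)
    svc = _fit_svc(_make_svc(C_best, gamma_best), Z, y)

    calib_slope, calib_intercept, calib_iso = _fit_calibration(
        X, y, tiv, C_best, gamma_best, use_confound_removal, s_calib, calibration
    )
    return PipelineModel(
        decomposition=dec,
        remover=rem,
        svc=svc,
        calib_slope=calib_slope,
        calib_intercept=calib_intercept,
        calib_iso=calib_iso,
        C=C_best,
        gamma=gamma_best,
        inner_cv_score=float(mean_scores[best]),
        n_train=len(y),
        n_features=X.shape[1],
        use_confound_removal=use_confound_removal,
    )


def _fit_calibration(X, y, tiv, C, gamma, use_cr, seed, method: str = "sigmoid",
                     n_folds: int = 5):
    """Calibration map from out-of-fold decision scores to P(male).

    Returns (slope, intercept, isotonic_map); the isotonic map is None for the
    sigmoid method and vice versa the affine parameters are (1, 0) identities
    when an isotonic map is fitted.
    """
    n_folds = min(n_folds, int(np.bincount(y).min()))
    if n_folds < 2:
        return 1.0, 0.0, None
    cv = StratifiedKFold(n_folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    for tr, te in cv.split(X, y):
        dec, rem, Ztr = _fit_stage(X[tr], None if tiv is None else tiv[tr], use_cr)
        svc = _fit_svc(_make_svc(C, gamma), Ztr, y[tr])
        Zte = dec.transform(X[te])
        if rem is not None:
            Zte = apply_confound_remover(rem, Zte, tiv[te])
        scores[te] = svc.decision_function(Zte)
    if method == "isotonic":
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
        iso.fit(scores, y)
        return 1.0, 0.0, iso
    lr = LogisticRegression(C=1e6, solver="lbfgs")
    lr.fit(scores[:, None], y)
    slope = float(lr.coef_[0, 0])
    if slope < 0:
        # a decreasing map would invert the score ordering; fall back to identity
        return 1.0, 0.0, None
    return slope, float(lr.intercept_[0]), None


def cross_validate(
    features: np.ndarray,
    labels,
    tiv: np.ndarray | None,
    space: HyperparameterSpace,
    use_confound_removal: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Nested stratified CV: tune within each outer fold, score on its test part.

    Returns one row per outer fold with the fold's balanced accuracy and the
    hyperparameters selected inside it; ``df.attrs['mean']`` / ``['sd']`` hold
    the summary.
    """
    X = np.asarray(features, float)
    y = _encode(labels)
    counts = np.bincount(y, minlength=2)
    if counts.min() < space.outer_folds:
        raise ValueError(
            f"outer {space.outer_folds}-fold CV infeasible with class counts {counts.tolist()}"
        )
    ss = np.random.SeedSequence(seed)
    s_outer = int(ss.generate_state(1)[0] % (2**31))
    fold_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(space.outer_folds)]
    outer = StratifiedKFold(space.outer_folds, shuffle=True, random_state=s_outer)
    rows = []
    for k, (tr, te) in enumerate(outer.split(X, y)):
        model = tune_and_train(
            X[tr], y[tr], None if tiv is None else np.asarray(tiv, float)[tr],
            space, use_confound_removal, seed=fold_seeds[k],
        )
        prob = model.predict_proba_male(X[te], None if tiv is None else np.asarray(tiv, float)[te])
        acc = balanced_accuracy_score(y[te], (prob >= 0.5).astype(int))
        rows.append({"fold": k, "n_test": len(te), "balanced_accuracy": float(acc),
                     "C": model.C, "gamma": model.gamma})
    df = pd.DataFrame(rows)
    df.attrs["mean"] = float(df["balanced_accuracy"].mean())
    df.attrs["sd"] = float(df["balanced_accuracy"].std(ddof=1)) if len(df) > 1 else 0.0
    return df


def assess_calibration(
    model: PipelineModel,
    features: np.ndarray,
    true_labels,
    tiv: np.ndarray | None = None,
    n_bins: int = 10,
) -> dict:
    """Reliability curve over equal-width probability bins, plus Brier score.

    Empty bins are absent from the curve rather than reported as zero.
    """
    y = _encode(true_labels)
    prob = model.predict_proba_male(features, tiv)
    return calibration_curve_from_probs(prob, y, n_bins)


def calibration_curve_from_probs(prob: np.ndarray, y: np.ndarray, n_bins: int = 10) -> dict:
    prob = np.asarray(prob, float)
    y = np.asarray(y, int)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(prob, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        rows.append({
            "bin": b,
            "mean_predicted": float(prob[mask].mean()),
            "observed_frequency": float(y[mask].mean()),
            "count": int(mask.sum()),
        })
    brier = float(np.mean((prob - y) ** 2))
    return {"curve": pd.DataFrame(rows), "brier": brier, "n": len(y)}


def predict(
    model: PipelineModel,
    features: np.ndarray,
    tiv: np.ndarray | None = None,
    ids=None,
    true_sex=None,
) -> pd.DataFrame:
    """Per-subject predictions: ``id true_sex pred_label prob_male``.

    ``pred_label`` is male iff the calibrated P(male) >= 0.5.  ``tiv`` is
    required when the model carries a confound remover.
    """
    X = np.asarray(features, float)
    prob = model.predict_proba_male(X, tiv)
    n = len(prob)
    out = pd.DataFrame(
        {
            "id": list(ids) if ids is not None else [f"s{i}" for i in range(n)],
            "true_sex": list(true_sex) if true_sex is not None else [""] * n,
            "pred_label": np.where(prob >= 0.5, "male", "female"),
            "prob_male": prob,
        }
    )
    return out


# --------------------------------------------------------------------------
# serialization

def save_model(model: PipelineModel, path: str | Path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "decomposition": {
            "mean": model.decomposition.mean,
            "loadings": model.decomposition.loadings,
            "n_components": model.decomposition.n_components,
        },
        "remover": None
        if model.remover is None
        else {
            "intercepts": model.remover.intercepts,
            "slopes": model.remover.slopes,
            "n_fit": model.remover.n_fit,
            "tiv_min": model.remover.tiv_min,
            "tiv_max": model.remover.tiv_max,
            "clip_extrapolation": model.remover.clip_extrapolation,
        },
        "svc": model.svc,
        "calib": (model.calib_slope, model.calib_intercept),
        "calib_iso": model.calib_iso,
        "hyperparameters": (model.C, model.gamma),
        "inner_cv_score": model.inner_cv_score,
        "train_descriptor": (model.n_train, model.n_features),
        "use_confound_removal": model.use_confound_removal,
        "meta": model.meta,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> PipelineModel:
    payload = joblib.load(path)
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema: {payload.get('schema_version')}")
    dec = DecompositionModel(**payload["decomposition"])
    rem = None if payload["remover"] is None else ConfoundRemover(**payload["remover"])
    C, gamma = payload["hyperparameters"]
    n_train, n_features = payload["train_descriptor"]
    return PipelineModel(
        decomposition=dec,
        remover=rem,
        svc=payload["svc"],
        calib_slope=payload["calib"][0],
        calib_intercept=payload["calib"][1],
        calib_iso=payload.get("calib_iso"),
        C=C,
        gamma=gamma,
        inner_cv_score=payload["inner_cv_score"],
        n_train=n_train,
        n_features=n_features,
        use_confound_removal=payload["use_confound_removal"],
        meta=payload.get("meta", {}),
    )
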