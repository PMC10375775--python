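"""Composite quality-index (QCEI) grading model.

The grading procedure runs in four steps on the pharmacopoeia-compliant
batches described by the 21 candidate quality indices:

1. a Mahalanobis confidence ellipsoid fitted to the premium + first-class
   training batches flags second-class material (outside the chi-square
   quantile boundary), after which grading premium vs first-class is a binary
   problem for a soft-margin RBF-kernel SVM whose hyperparameters (C over
   e^-5..e^5, gamma over 10^-5..10^5, 21 log-steps each) are chosen by
   stratified tenfold cross-validation;
2. with the trained duals frozen, each feature is removed from the kernel in
   turn and the absolute change of the dual objective (DJ) is recorded --
   the SVM-RFE ranking criterion;
3. DJ values normalized to percentages are the feature contributions; the
   top-k (default 9) features are kept and the SVM re-tuned on the subset;
4. a Platt sigmoid fitted to cross-validated decision values turns the
   margin into a posterior probability of premium grade, which a piecewise-
   linear map places on the 70-100 QCEI scale: premium (p >= 0.5) scores
   86 + 28*(p - 0.5) in [86, 100], first-class scores 70 + 30*p in [70, 85);
   batches outside the confidence boundary are second-class and score below
   70, decaying monotonically with boundary distance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .synthdata import INDEX_ORDER

__all__ = [
    "Boundary",
    "SvmGradeModel",
    "PlattCalibration",
    "QceiResult",
    "PipelineResult",
    "default_c_grid",
    "default_gamma_grid",
    "fit_boundary",
    "train_svm",
    "dual_objective",
    "dj_contributions",
    "grid_search",
    "select_top_features",
    "platt_fit",
    "qcei_score",
    "run_full_pipeline",
]

logger = logging.getLogger("licograde")

_KKT_TOL = 1e-5


def default_c_grid(points: int = 21) -> np.ndarray:
    """Box-penalty grid: e^-5 .. e^5 in ``points`` log-steps."""
    return np.exp(np.linspace(-5.0, 5.0, points))


def default_gamma_grid(points: int = 21) -> np.ndarray:
    """RBF-width grid: 10^-5 .. 10^5 in ``points`` log-steps."""
    return 10.0 ** np.linspace(-5.0, 5.0, points)


# ---------------------------------------------------------------------------
# Confidence boundary (second-class pre-screen)
# ---------------------------------------------------------------------------


@dataclass
class Boundary:
    """Mahalanobis confidence ellipsoid with a chi-square cutoff.

    A point is inside when its squared Mahalanobis distance to the training
    mean is at most ``chi2.ppf(q, df=n_features)``.
    """

    center: np.ndarray
    covariance: np.ndarray
    cutoff: float  # squared-distance threshold
    quantile: float
    ridge: float = 0.0
    _chol: np.ndarray = field(default=None, repr=False)

    def distance2(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        delta = X - self.center
        z = linalg.cho_solve(( self._chol, True), delta.T)
        return np.einsum("ij,ji->i", delta, z)

    def contains(self, X) -> np.ndarray:
        return self.distance2(X) <= self.cutoff


def fit_boundary(X, quantile: float = 0.99, ridge: float | None = None) -> Boundary:
    """Fit the confidence ellipsoid to the premium + first-class training
    block: sample mean, (ridge-regularized if singular) sample covariance,
    cutoff at the chi-square ``quantile`` with df = feature count."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} rows to fit a {p}-feature boundary, got {n}")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    center = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    eigvals = np.linalg.eigvalsh(cov)
    lam = 0.0
    if ridge is not None:
        lam = ridge
    elif eigvals[0] <= 1e-10 * max(eigvals[-1], 1.0):
        lam = 1e-8 * np.trace(cov) / p
        logger.warning("singular covariance; ridge-regularized with lambda=%.3g", lam)
    if lam:
        cov = cov + lam * np.eye(p)
    chol = linalg.cholesky(cov, lower=True)
    b = Boundary(
        center=center,
        covariance=cov,
        cutoff=float(stats.chi2.ppf(quantile, df=p)),
        quantile=quantile,
        ridge=lam,
    )
    b._chol = chol
    return b


# ---------------------------------------------------------------------------
# Soft-margin RBF SVM
# ---------------------------------------------------------------------------


@dataclass
class SvmGradeModel:
    """Trained soft-margin RBF SVM with its dual solution exposed.

    Decision function f(x) = sum_i alpha_i y_i K(x_i, x) + b with
    K(x, z) = exp(-gamma ||x - z||^2); labels are +1 (premium) and -1
    (first-class).  Features are z-scored by the stored scaler before the
    kernel.
    """

    C: float
    gamma: float
    alphas: np.ndarray  # full-length duals, 0 off the support set
    y: np.ndarray  # training labels, +-1
    b: float
    support: np.ndarray  # indices of support vectors
    X_train: np.ndarray  # scaled training matrix
    feature_subset: tuple[str, ...]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray

    def scale(self, X) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_sd

    def decision_function(self, X, scaled: bool = False) -> np.ndarray:
        Xs = np.atleast_2d(X if scaled else self.scale(X))
        K = rbf_kernel(Xs, self.X_train, gamma=self.gamma)
        return K @ (self.alphas * self.y) + self.b

    def kkt_violation(self) -> float:
        box = max(0.0, float(np.max(-self.alphas)), float(np.max(self.alphas - self.C)))
        eq = abs(float(self.alphas @ self.y))
        return max(box / max(self.C, 1.0), eq / max(self.C, 1.0))


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


def train_svm(
    X,
    y,
    C: float,
    gamma: float,
    feature_subset: tuple[str, ...] | None = None,
    scale: bool = True,
) -> SvmGradeModel:
    """Solve the soft-margin dual for an RBF SVM and expose alpha, b and the
    support set.

    The quadratic program is delegated to libsvm (via scikit-learn); the KKT
    conditions (0 <= alpha_i <= C, sum alpha_i y_i = 0) are asserted post-hoc
    to ``1e-5 * C``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    if not np.array_equal(np.sort(classes), [-1, 1]):
        raise ValueError("labels must be coded +-1 (+1 premium, -1 first-class)")
    if scale:
        mean, sd = _fit_scaler(X)
    else:
        mean, sd = np.zeros(X.shape[1]), np.ones(X.shape[1])
    Xs = (X - mean) / sd

    svc = SVC(C=C, kernel="rbf", gamma=gamma, tol=1e-6, shrinking=True)
    svc.fit(Xs, y)
    alphas = np.zeros(len(y))
    # dual_coef_ holds alpha_i * y_i for the support vectors
    alphas[svc.support_] = np.abs(svc.dual_coef_.ravel())
    model = SvmGradeModel(
        C=float(C),
        gamma=float(gamma),
        alphas=alphas,
        y=y.astype(float),
        b=float(svc.intercept_[0]),
        support=svc.support_.copy(),
        X_train=Xs,
        feature_subset=tuple(feature_subset) if feature_subset is not None else tuple(
            f"x{i}" for i in range(X.shape[1])
        ),
        scaler_mean=mean,
        scaler_sd=sd,
    )
    if model.kkt_violation() > _KKT_TOL:
        raise RuntimeError(f"KKT violation {model.kkt_violation():.2e} exceeds {_KKT_TOL}")
    return model


def dual_objective(alphas, y, K) -> float:
    """SVM dual objective J(alpha) = sum_i alpha_i - 1/2 sum_ij alpha_i
    alpha_j y_i y_j K_ij."""
    alphas = np.asarray(alphas, dtype=float)
    y = np.asarray(y, dtype=float)
    K = np.asarray(K, dtype=float)
    if K.shape != (alphas.size, alphas.size) or y.size != alphas.size:
        raise ValueError(
            f"dimension mismatch: alpha {alphas.shape}, y {y.shape}, K {K.shape}"
        )
    beta = alphas * y
    return float(alphas.sum() - 0.5 * beta @ K @ beta)


def dj_contributions(model: SvmGradeModel) -> pd.DataFrame:
    """Leave-one-feature-out change of the dual objective (DJ) with the
    trained duals frozen, normalized to percentage contributions.

    For feature f, DJ_f = | 1/2 sum_ij alpha_i alpha_j y_i y_j
    (K_ij - K^(-f)_ij) | where K^(-f) is the RBF kernel on the training data
    without column f (same gamma, same alphas).  A constant (zero-variance)
    feature leaves the kernel unchanged and has DJ exactly 0.
    """
    sv = model.support
    Xs = model.X_train[sv]
    beta = (model.alphas * model.y)[sv]
    gamma = model.gamma
    # K^(-f) = K * exp(gamma * d_f^2) where d_f is the column-f difference
    d2 = ((Xs[:, None, :] - Xs[None, :, :]) ** 2)
    K = np.exp(-gamma * d2.sum(axis=2))
    djs = np.empty(Xs.shape[1])
    for f in range(Xs.shape[1]):
        K_minus = K * np.exp(gamma * d2[:, :, f])
        djs[f] = abs(0.5 * beta @ (K - K_minus) @ beta)
    total = djs.sum()
    if total == 0:
        raise ValueError("all DJ values are zero; contributions undefined")
    return pd.DataFrame(
        {
            "index": list(model.feature_subset),
            "dj": djs,
            "contribution": 100.0 * djs / total,
        }
    )


# ---------------------------------------------------------------------------
# Hyperparameter grid search
# ---------------------------------------------------------------------------


def _stratified_folds(y: np.ndarray, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    _, counts = np.unique(y, return_counts=True)
    min_count = int(counts.min())
    if min_count < 2:
        raise ValueError("a class has fewer than 2 members; cannot stratify")
    if folds > min_count:
        warnings.warn(
            f"reducing folds from {folds} to {min_count} (smallest class size)",
            stacklevel=3,
        )
        folds = min_count
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def grid_search(
    X,
    y,
    C_grid=None,
    gamma_grid=None,
    folds: int = 10,
    seed: int = 0,
    scale: bool = True,
) -> tuple[float, float, float]:
    """Pick (C, gamma) by pooled stratified k-fold cross-validation accuracy.

    Scaling is fitted on each training fold.  Ties are broken toward the
    smaller C, then the smaller gamma, so the result is deterministic given
    the seed.  Returns (C*, gamma*, cv_accuracy) with accuracy as a fraction.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    C_grid = default_c_grid() if C_grid is None else np.asarray(C_grid, dtype=float)
    gamma_grid = (
        default_gamma_grid() if gamma_grid is None else np.asarray(gamma_grid, dtype=float)
    )
    if C_grid.size == 0 or gamma_grid.size == 0:
        raise ValueError("empty hyperparameter grid")
    splits = _stratified_folds(y, folds, seed)
    correct = np.zeros((C_grid.size, gamma_grid.size), dtype=int)
    for train_idx, test_idx in splits:
        Xtr, ytr = X[train_idx], y[train_idx]
        Xte, yte = X[test_idx], y[test_idx]
        if scale:
            mean, sd = _fit_scaler(Xtr)
            Xtr = (Xtr - mean) / sd
            Xte = (Xte - mean) / sd
        for ci, C in enumerate(C_grid):
            for gi, g in enumerate(gamma_grid):
                svc = SVC(C=C, kernel="rbf", gamma=g)
                svc.fit(Xtr, ytr)
                correct[ci, gi] += int((svc.predict(Xte) == yte).sum())
    # argmax with ties toward smaller C then smaller gamma: C-major scan order
    flat = np.argmax(correct)  # first occurrence wins in row-major order
    ci, gi = np.unravel_index(flat, correct.shape)
    accuracy = correct[ci, gi] / len(y)
    return float(C_grid[ci]), float(gamma_grid[gi]), float(accuracy)


def select_top_features(contributions: pd.DataFrame, k: int = 9) -> tuple[str, ...]:
    """Top-k feature names by contribution; ties keep the original (reporting)
    order."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(contributions):
        raise ValueError(f"k={k} exceeds feature count {len(contributions)}")
    order = np.argsort(-contributions["contribution"].to_numpy(), kind="stable")
    return tuple(contributions["index"].to_numpy()[order[:k]])


# ---------------------------------------------------------------------------
# Platt sigmoid calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlattCalibration:
    """Sigmoid posterior p(f) = 1 / (1 + exp(A f + B))."""

    A: float
    B: float

    def posterior(self, f) -> np.ndarray:
        z = self.A * np.asarray(f, dtype=float) + self.B
        # numerically safe logistic
        out = np.where(z >= 0, np.exp(-np.clip(z, 0, None)) / (1.0 + np.exp(-np.clip(z, 0, None))),
                       1.0 / (1.0 + np.exp(np.clip(z, None, 0))))
        return out if out.ndim else float(out)


def platt_fit(decision_values, labels, max_iter: int = 200, grad_tol: float = 1e-8) -> PlattCalibration:
    """Fit the Platt sigmoid to decision values by regularized maximum
    likelihood.

    Targets are smoothed as t+ = (N+ + 1)/(N+ + 2) and t- = 1/(N- + 2), and
    (A, B) minimize the cross-entropy by Newton's method with backtracking,
    iterated to gradient norm < ``grad_tol``.
    """
    f = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels)
    if not np.all(np.isfinite(f)):
        raise ValueError("non-finite decision values")
    pos = y == (1 if 1 in np.unique(y) else np.unique(y).max())
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    t = np.where(pos, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    # with p = 1/(1+e^z), z = A f + B: NLL = sum log(1+e^z) - (1-t) z
    s = 1.0 - t

    A, B = 0.0, float(np.log((n_neg + 1.0) / (n_pos + 1.0)))

    def objective(a, b):
        z = a * f + b
        return float(np.sum(np.logaddexp(0.0, z) - s * z))

    obj = objective(A, B)
    for _ in range(max_iter):
        z = A * f + B
        p = PlattCalibration(1.0, 0.0).posterior(-z)  # sigma(z) = 1/(1+e^-z)
        # gradient of sum log(1+e^z) - (1-t) z  w.r.t. (A, B)
        d = p - s
        g = np.array([d @ f, d.sum()])
        if np.linalg.norm(g, ord=np.inf) < grad_tol:
            break
        w = np.maximum(p * (1.0 - p), 1e-12)
        h11 = w @ (f * f)
        h12 = w @ f
        h22 = w.sum()
        det = h11 * h22 - h12 * h12
        if det <= 0:
            det = max(det, 1e-12)
        dA = -(h22 * g[0] - h12 * g[1]) / det
        dB = -(-h12 * g[0] + h11 * g[1]) / det
        step = 1.0
        while step > 1e-10:
            cand = objective(A + step * dA, B + step * dB)
            if cand <= obj + 1e-4 * step * (g[0] * dA + g[1] * dB):
                A, B, obj = A + step * dA, B + step * dB, cand
                break
            step /= 2.0
        else:
            break
    return PlattCalibration(A=float(A), B=float(B))


# ---------------------------------------------------------------------------
# QCEI score mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QceiResult:
    """Scored batch: posterior premium probability, predicted grade and the
    QCEI score (premium in [86, 100], first-class in [70, 85), second-class
    below 70)."""

    batch_id: str
    posterior: float
    predicted_grade: str
    qcei: float
    boundary_distance: float = np.nan

    @property
    def display_score(self) -> str:
        return "<70" if self.predicted_grade == "second" else f"{self.qcei:.1f}"


def qcei_score(
    posterior: float,
    inside_boundary: bool,
    batch_id: str = "",
    boundary_distance: float = np.nan,
    boundary_cutoff: float = np.nan,
) -> QceiResult:
    """Map a calibrated posterior into the 70-100 QCEI bands.

    Inside the confidence boundary: p >= 0.5 is premium with score
    86 + 28*(p - 0.5); p < 0.5 is first-class with score 70 + 30*p.  The map
    is monotone in p and its band edges (86 floor, 85 ceiling) match the
    printed grade ranges.  Outside the boundary the batch is second-class and
    scores 70 * sqrt(cutoff / d^2) < 70, decaying with the squared
    Mahalanobis distance d^2.
    """
    if not 0.0 <= posterior <= 1.0:
        raise ValueError(f"posterior {posterior} outside [0, 1]")
    if not inside_boundary:
        if np.isfinite(boundary_distance) and np.isfinite(boundary_cutoff) and boundary_distance > 0:
            score = 70.0 * float(np.sqrt(boundary_cutoff / boundary_distance))
        else:
            score = 69.0
        score = min(score, 70.0 - 1e-9)
        return QceiResult(batch_id, float(posterior), "second", score, boundary_distance)
    if posterior >= 0.5:
        return QceiResult(
            batch_id, float(posterior), "premium", 86.0 + 28.0 * (posterior - 0.5), boundary_distance
        )
    return QceiResult(
        batch_id, float(posterior), "first", 70.0 + 30.0 * posterior, boundary_distance
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    model: SvmGradeModel  # retrained top-k model
    model_full: SvmGradeModel  # all-candidate model
    contributions: pd.DataFrame  # index, dj, contribution (%)
    scores: pd.DataFrame  # batch_id, posterior, predicted_grade, qcei, ...
    boundary: Boundary
    calibration: PlattCalibration
    cv_report: dict


def run_full_pipeline(
    features: pd.DataFrame,
    feature_columns: tuple[str, ...] = INDEX_ORDER,
    label_column: str = "true_grade",
    top_k: int = 9,
    folds: int = 10,
    boundary_quantile: float = 0.99,
    C_grid=None,
    gamma_grid=None,
    seed: int = 0,
    min_class_size: int = 20,
) -> PipelineResult:
    """Run the four grading steps end to end on a compliant feature table.

    ``features`` must carry ``batch_id``, the candidate index columns and a
    label column with grades in {premium, first, second}.  The SVM is trained
    on premium vs first-class; second-class is pre-screened by the confidence
    boundary.  Deterministic given ``seed``.
    """
    feature_columns = tuple(feature_columns)
    missing = [c for c in feature_columns if c not in features.columns]
    if missing:
        raise ValueError(f"feature table is missing index columns: {missing}")
    grades = features[label_column]
    train_mask = grades.isin(["premium", "first"]).to_numpy()
    n_premium = int((grades == "premium").sum())
    n_first = int((grades == "first").sum())
    if min(n_premium, n_first) < min_class_size:
        raise ValueError(
            f"need >= {min_class_size} batches per class for stable CV "
            f"(premium={n_premium}, first={n_first})"
        )

    X_all = features.loc[:, list(feature_columns)].to_numpy(dtype=float)
    X_train = X_all[train_mask]
    y_train = np.where(grades[train_mask] == "premium", 1, -1)

    logger.info("stage=boundary fitting %d-feature ellipsoid (q=%.2f)", X_train.shape[1], boundary_quantile)
    boundary = fit_boundary(X_train, quantile=boundary_quantile)

    logger.info("stage=grid_search features=%d", len(feature_columns))
    C1, g1, acc1 = grid_search(X_train, y_train, C_grid, gamma_grid, folds=folds, seed=seed)
    logger.info("stage=grid_search C=%.4g gamma=%.4g cv_accuracy=%.4f", C1, g1, acc1)
    model_full = train_svm(X_train, y_train, C1, g1, feature_subset=feature_columns)

    logger.info("stage=dj_contributions")
    contributions = dj_contributions(model_full)
    subset = select_top_features(contributions, k=top_k)

    sub_idx = [feature_columns.index(name) for name in subset]
    X_train_sub = X_train[:, sub_idx]
    logger.info("stage=grid_search features=%d (retrain)", top_k)
    C2, g2, acc2 = grid_search(X_train_sub, y_train, C_grid, gamma_grid, folds=folds, seed=seed)
    logger.info("stage=grid_search C=%.4g gamma=%.4g cv_accuracy=%.4f", C2, g2, acc2)
    model = train_svm(X_train_sub, y_train, C2, g2, feature_subset=subset)

    # Platt sigmoid on cross-validated decision values of the retrained model
    logger.info("stage=platt_fit")
    cv_decisions = np.empty(len(y_train))
    for tr, te in _stratified_folds(y_train, folds, seed):
        fold_model = train_svm(X_train_sub[tr], y_train[tr], C2, g2)
        cv_decisions[te] = fold_model.decision_function(X_train_sub[te])
    calibration = platt_fit(cv_decisions, y_train)

    # score every compliant batch
    logger.info("stage=qcei_score n=%d", len(features))
    d2 = boundary.distance2(X_all)
    inside = d2 <= boundary.cutoff
    f_all = model.decision_function(X_all[:, sub_idx])
    p_all = np.asarray(calibration.posterior(f_all))
    results = [
        qcei_score(
            p_all[i],
            bool(inside[i]),
            batch_id=str(features["batch_id"].iloc[i]),
            boundary_distance=float(d2[i]),
            boundary_cutoff=boundary.cutoff,
        )
        for i in range(len(features))
    ]
    scores = pd.DataFrame(
        {
            "batch_id": [r.batch_id for r in results],
            "posterior": [r.posterior for r in results],
            "predicted_grade": [r.predicted_grade for r in results],
            "qcei": [r.qcei for r in results],
            "boundary_distance2": [r.boundary_distance for r in results],
        }
    )
    if label_column in features.columns:
        scores[label_column] = features[label_column].to_numpy()

    cv_report = {
        "C_full": C1,
        "gamma_full": g1,
        "cv_accuracy_full_pct": 100.0 * acc1,
        "C_subset": C2,
        "gamma_subset": g2,
        "cv_accuracy_subset_pct": 100.0 * acc2,
        "n_train": int(len(y_train)),
        "n_features_full": len(feature_columns),
        "n_features_subset": top_k,
        "seed": seed,
        "folds": folds,
    }
    return PipelineResult(
        model=model,
        model_full=model_full,
        contributions=contributions,
        scores=scores,
        boundary=boundary,
        calibration=calibration,
        cv_report=cv_report,
    )
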