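"""PLS-DA genotype classification of Raman spectra.

Spectra are fingerprint-AUC normalised, split into calibration and
validation sets by removing every fourth spectrum, and classified with a
PLS2 model (NIPALS, one-hot class targets, argmax decision) using 7
latent variables.  Cross-validation uses venetian blinds with 10 data
splits.  Variable-importance-in-projection (VIP) scores rank wavenumbers
by their contribution to the class separation; for fumarate-driven
separations the 1277/1401/1652 cm^-1 triplet dominates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .core import validate_axis

__all__ = [
    "LabelledSpectra",
    "PLSDAModel",
    "split_every_fourth",
    "venetian_blind_folds",
    "fit_plsda",
    "vip_scores",
    "evaluate_classification",
]


@dataclass
class LabelledSpectra:
    """A matrix of spectra with one class label per row."""

    X: np.ndarray                 # (n, channels)
    labels: np.ndarray            # (n,) class names
    wavenumbers: np.ndarray
    dwell: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        self.wavenumbers = validate_axis(self.wavenumbers)
        if self.X.ndim != 2 or self.X.shape[1] != self.wavenumbers.size:
            raise ValueError("X must be (n_spectra, n_channels)")
        if self.labels.shape != (self.X.shape[0],):
            raise ValueError("one label per spectrum required")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset(self, idx) -> "LabelledSpectra":
        return LabelledSpectra(self.X[idx], self.labels[idx],
                               self.wavenumbers, dwell=self.dwell,
                               meta=dict(self.meta))


def split_every_fourth(data: LabelledSpectra
                       ) -> tuple[LabelledSpectra, LabelledSpectra]:
    """Every fourth spectrum (positions 4, 8, ... 1-based) forms the
    validation set; the remainder is the calibration set.  Order is
    preserved within both sets."""
    n = len(data)
    if n < 4:
        raise ValueError("need at least 4 spectra to split")
    idx = np.arange(n)
    val = idx[3::4]
    cal = np.setdiff1d(idx, val)
    return data.subset(cal), data.subset(val)


def venetian_blind_folds(n: int, n_splits: int = 10) -> list[np.ndarray]:
    """Fold f holds positions f, f + n_splits, f + 2 n_splits, ..."""
    return [np.arange(f, n, n_splits) for f in range(min(n_splits, n))]


class _GaussianScores:
    """Gaussian class-conditional model on the PLS latent scores: the
    multivariate analogue of the per-class Bayesian score threshold used
    by chemometrics toolboxes.  Regularised full covariance per class."""

    def __init__(self, shrinkage: float = 1e-2) -> None:
        self.shrinkage = shrinkage

    def fit(self, T: np.ndarray, labels: np.ndarray,
            classes: np.ndarray) -> "_GaussianScores":
        self.classes_ = classes
        self.means_, self.precisions_, self.logdets_ = [], [], []
        p = T.shape[1]
        for c in classes:
            S = T[labels == c]
            mu = S.mean(axis=0)
            cov = np.atleast_2d(np.cov(S, rowvar=False))
            ridge = max(self.shrinkage * np.trace(cov) / p, 1e-12)
            cov = cov + ridge * np.eye(p)
            self.means_.append(mu)
            self.precisions_.append(np.linalg.inv(cov))
            self.logdets_.append(np.linalg.slogdet(cov)[1])
        return self

    def log_likelihood(self, T: np.ndarray) -> np.ndarray:
        out = np.empty((T.shape[0], len(self.classes_)))
        for j, (mu, prec, logdet) in enumerate(
                zip(self.means_, self.precisions_, self.logdets_)):
            d = T - mu
            out[:, j] = -0.5 * (np.einsum("ni,ij,nj->n", d, prec, d)
                                + logdet)
        return out


@dataclass
class PLSDAModel:
    classes: np.ndarray
    n_latent: int
    pls: PLSRegression
    wavenumbers: np.ndarray
    x_mean: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    decision: str = "bayes"
    gaussian: _GaussianScores | None = None
    cv_confusion: np.ndarray | None = None
    cv_metrics: dict | None = None
    meta: dict = field(default_factory=dict)

    def _prep(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.x_mean is not None:
            X = (X - self.x_mean) / self.x_scale
        return X

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Predicted one-hot class scores (regression outputs)."""
        return self.pls.predict(self._prep(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xp = self._prep(X)
        if self.decision == "bayes" and self.gaussian is not None:
            ll = self.gaussian.log_likelihood(self.pls.transform(Xp))
            return self.classes[np.argmax(ll, axis=1)]
        return self.classes[np.argmax(self.pls.predict(Xp), axis=1)]


def _one_hot(labels: np.ndarray, classes: np.ndarray) -> np.ndarray:
    Y = np.zeros((labels.size, classes.size))
    for j, c in enumerate(classes):
        Y[labels == c, j] = 1.0
    return Y


def _confusion(true: np.ndarray, pred: np.ndarray,
               classes: np.ndarray) -> np.ndarray:
    k = classes.size
    cm = np.zeros((k, k), dtype=int)
    lut = {c: i for i, c in enumerate(classes)}
    for t, p in zip(true, pred):
        cm[lut[t], lut[p]] += 1
    return cm


def _metrics_from_confusion(cm: np.ndarray, classes: np.ndarray) -> dict:
    """One-vs-rest sensitivity and specificity per class."""
    total = cm.sum()
    out: dict[str, dict[str, float | None]] = {}
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if (tp + fn) > 0 else None
        spec = tn / (tn + fp) if (tn + fp) > 0 else None
        if sens is None:
            warnings.warn(f"class {c!r} absent; sensitivity undefined")
        out[str(c)] = {"sensitivity": sens, "specificity": spec}
    return out


def _fit_one(X: np.ndarray, labels: np.ndarray, classes: np.ndarray,
             n_latent: int, decision: str
             ) -> tuple[PLSRegression, _GaussianScores | None]:
    Y = _one_hot(labels, classes)
    pls = PLSRegression(n_components=n_latent, scale=False)
    pls.fit(X, Y)
    gaussian = None
    if decision == "bayes":
        gaussian = _GaussianScores().fit(pls.transform(X), labels, classes)
    return pls, gaussian


def fit_plsda(cal: LabelledSpectra, n_latent: int = 7, cv_splits: int = 10,
              autoscale: bool = True, decision: str = "bayes") -> PLSDAModel:
    """Fit the PLS-DA model and compute venetian-blinds CV metrics.

    Spectra are autoscaled (per-channel standardisation) by default, the
    usual chemometrics preprocessing; PLS2 is fitted on one-hot class
    targets with ``n_latent`` components.  ``decision`` selects the
    classification rule on new spectra: 'bayes' (default; Gaussian
    class-conditional model on the latent scores) or 'argmax' (raw
    argmax of the predicted class scores).
    """
    if decision not in ("bayes", "argmax"):
        raise ValueError("decision must be 'bayes' or 'argmax'")
    classes = cal.classes
    if classes.size < 2:
        raise ValueError("PLS-DA needs at least two classes")
    n, p = cal.X.shape
    if n_latent >= min(n, p):
        raise ValueError("n_latent must be below min(n_samples, n_channels)")
    if autoscale:
        x_mean = cal.X.mean(axis=0)
        x_scale = cal.X.std(axis=0)
        x_scale[x_scale == 0] = 1.0
    else:
        x_mean = np.zeros(p)
        x_scale = np.ones(p)
    X = (cal.X - x_mean) / x_scale
    pls, gaussian = _fit_one(X, cal.labels, classes, n_latent, decision)

    cv_conf = None
    cv_metrics = None
    if cv_splits and cv_splits >= 2:
        preds = np.empty(n, dtype=cal.labels.dtype)
        for fold in venetian_blind_folds(n, cv_splits):
            train = np.setdiff1d(np.arange(n), fold)
            if autoscale:   # preprocessing recomputed inside each fold
                mu = cal.X[train].mean(axis=0)
                sc = cal.X[train].std(axis=0)
                sc[sc == 0] = 1.0
            else:
                mu, sc = x_mean, x_scale
            sub = PLSDAModel(classes=classes,
                             n_latent=min(n_latent, train.size - 1),
                             pls=None, wavenumbers=cal.wavenumbers,
                             x_mean=mu, x_scale=sc, decision=decision)
            sub.pls, sub.gaussian = _fit_one(
                (cal.X[train] - mu) / sc, cal.labels[train], classes,
                sub.n_latent, decision)
            preds[fold] = sub.predict(cal.X[fold])
        cv_conf = _confusion(cal.labels, preds, classes)
        cv_metrics = _metrics_from_confusion(cv_conf, classes)

    return PLSDAModel(classes=classes, n_latent=n_latent, pls=pls,
                      wavenumbers=cal.wavenumbers, x_mean=x_mean,
                      x_scale=x_scale, decision=decision, gaussian=gaussian,
                      cv_confusion=cv_conf, cv_metrics=cv_metrics,
                      meta={"cv": f"venetian-blinds-{cv_splits}",
                            "autoscale": autoscale})


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """Variable importance in projection per wavenumber.

    VIP_j = sqrt( p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a ), where
    SS_a is the class-target variance explained by latent variable a.
    The scores satisfy sum_j VIP_j^2 = p exactly.
    """
    pls = getattr(model, "pls", None)
    if pls is None or not hasattr(pls, "x_weights_"):
        raise ValueError("model must be fitted before computing VIP scores")
    W = pls.x_weights_            # (p, A)
    T = pls.x_scores_             # (n, A)
    Q = pls.y_loadings_           # (m, A)
    p, A = W.shape
    ss = np.einsum("na,na->a", T, T) * np.einsum("ma,ma->a", Q, Q)
    Wn2 = (W / np.linalg.norm(W, axis=0, keepdims=True)) ** 2
    vip = np.sqrt(p * (Wn2 @ ss) / ss.sum())
    return vip


def evaluate_classification(model: PLSDAModel, val: LabelledSpectra) -> dict:
    """Per-class one-vs-rest sensitivity/specificity on a validation set."""
    if len(val) == 0:
        raise ValueError("validation set is empty")
    pred = model.predict(val.X)
    cm = _confusion(val.labels, pred, model.classes)
    metrics = _metrics_from_confusion(cm, model.classes)
    metrics["confusion"] = cm
    return metrics
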