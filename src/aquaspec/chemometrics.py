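"""NIPALS PLS1 regression with leave-one-out cross-validation.

The day-of-stress model regresses a single response (day of chilling) on
second-derivative spectra.  :class:`NipalsPls` is a scikit-learn style
regressor implementing the classical NIPALS algorithm for one response:
per latent variable (LV) the weight vector w maximises covariance between
X-scores and the centred response, X is deflated by the rank-one score ×
loading contribution, and the regression vector is assembled as
b = W (PᵀW)⁻¹ q.

Model selection follows the standard chemometric protocol: leave-one-out
cross-validation over a range of LV counts; the chosen LV count is the
(first) minimiser of SECV.  Reported statistics:

* SEC  — standard error of calibration, sqrt(RSS / (n − n_lv − 1));
* SECV — standard error of cross-validation, RMS of LOO residuals;
* SEP  — standard error of prediction on an untouched validation set (RMS);
* R    — Pearson correlation between reference and predicted values
  (Rcal / Rcv / Rval for the three sets).
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np

from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .spectra import SpectraSet, select_subset

_TINY = 1e-14


class NipalsPls(RegressorMixin, BaseEstimator):
    """PLS1 regression fitted by NIPALS with X-deflation.

    Parameters
    ----------
    n_components : int
        Number of latent variables requested.
    tol : float
        Convergence tolerance on the weight vector (relevant for the
        iterative multi-response loop; PLS1 converges in one pass).
    max_iter : int
        Iteration cap per latent variable.
    deflate_y : bool
        Also deflate the response after each LV.  For a single response
        this does not change the model; kept for completeness.

    Attributes
    ----------
    x_mean_, y_mean_ : centering vectors.
    x_weights_ : ndarray (n_channels, k) — W.
    x_loadings_ : ndarray (n_channels, k) — P.
    y_loadings_ : ndarray (k,) — q.
    coef_ : ndarray (n_channels,) — regression vector b at the full LV count.
    coef_path_ : ndarray (n_channels, k) — b using 1..k LVs (nested models).
    n_components_ : int — LVs actually extracted (< requested if X is rank
        deficient; the coefficient path is padded with the last column).
    """

    def __init__(self, n_components=2, tol=1e-12, max_iter=500, deflate_y=False):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.deflate_y = deflate_y

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if y.size != n:
            raise ValueError("X and y have incompatible lengths")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("X and y must be finite")
        if np.std(y) == 0:
            raise ValueError("response has zero variance")
        K = int(self.n_components)
        if K < 1 or K > min(n - 1, p):
            raise ValueError(
                f"n_components={K} must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}]"
            )

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xd = X - self.x_mean_
        yd = y - self.y_mean_

        W = np.zeros((p, K))
        P = np.zeros((p, K))
        q = np.zeros(K)
        T = np.zeros((n, K))
        k_eff = 0
        for k in range(K):
            # NIPALS inner loop: u = (deflated) y for a single response, so
            # w converges on the first pass; the loop guards the general case.
            u = yd
            w = Xd.T @ u
            for _ in range(self.max_iter):
                nw = np.linalg.norm(w)
                if nw < _TINY:
                    break
                w_dir = w / nw
                w_new = Xd.T @ u
                if np.linalg.norm(w_new / max(np.linalg.norm(w_new), _TINY) - w_dir) < self.tol:
                    w = w_new
                    break
                w = w_new
            nw = np.linalg.norm(w)
            if nw < _TINY:
                break
            w = w / nw
            t = Xd @ w
            tt = t @ t
            if tt < _TINY:
                break
            p_vec = (Xd.T @ t) / tt
            qk = (yd @ t) / tt
            Xd = Xd - np.outer(t, p_vec)
            if self.deflate_y:
                yd = yd - qk * t
            W[:, k], P[:, k], q[k], T[:, k] = w, p_vec, qk, t
            k_eff = k + 1

        if k_eff == 0:
            raise ValueError("X has no covariance with y; no latent variable extracted")
        if k_eff < K:
            warnings.warn(
                f"rank exhausted after {k_eff} latent variables (requested {K})"
            )
        W, P, q = W[:, :k_eff], P[:, :k_eff], q[:k_eff]

        coef_path = np.zeros((p, K))
        PtW = P.T @ W
        for k in range(k_eff):
            bk = W[:, : k + 1] @ np.linalg.solve(
                PtW[: k + 1, : k + 1], q[: k + 1]
            )
            coef_path[:, k] = bk
        for k in range(k_eff, K):
            coef_path[:, k] = coef_path[:, k_eff - 1]

        self.x_weights_ = W
        self.x_loadings_ = P
        self.y_loadings_ = q
        self.x_scores_ = T[:, :k_eff]
        self.coef_path_ = coef_path
        self.coef_ = coef_path[:, K - 1]
        self.n_components_ = k_eff
        self.n_features_in_ = p
        return self

    def predict(self, X, n_components=None):
        check_is_fitted(self, "coef_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} channels; model was trained with {self.n_features_in_}"
            )
        b = (
            self.coef_
            if n_components is None
            else self.coef_path_[:, int(n_components) - 1]
        )
        return (X - self.x_mean_) @ b + self.y_mean_

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "format": "aquaspec-pls",
            "version": 1,
            "params": self.get_params(),
            "x_mean": self.x_mean_.tolist(),
            "y_mean": self.y_mean_,
            "x_weights": self.x_weights_.tolist(),
            "x_loadings": self.x_loadings_.tolist(),
            "y_loadings": self.y_loadings_.tolist(),
            "coef": self.coef_.tolist(),
            "n_components_extracted": self.n_components_,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "NipalsPls":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("format") != "aquaspec-pls":
            raise ValueError("not an aquaspec PLS model file")
        m = cls(**d["params"])
        m.x_mean_ = np.array(d["x_mean"])
        m.y_mean_ = float(d["y_mean"])
        m.x_weights_ = np.array(d["x_weights"])
        m.x_loadings_ = np.array(d["x_loadings"])
        m.y_loadings_ = np.array(d["y_loadings"])
        m.coef_ = np.array(d["coef"])
        m.n_components_ = int(d["n_components_extracted"])
        m.n_features_in_ = m.coef_.size
        K = int(m.get_params()["n_components"])
        path_mat = np.tile(m.coef_[:, None], (1, K))
        m.coef_path_ = path_mat
        return m


def regression_vector(model: NipalsPls) -> np.ndarray:
    """The fitted regression vector b over channels (for plots/peak-finding)."""
    check_is_fitted(model, "coef_")
    return model.coef_.copy()


# ---------------------------------------------------------------------------
# calibration / validation protocol
# ---------------------------------------------------------------------------

#: plant split used throughout: 7 calibration plants and 3 validation plants
DEFAULT_CAL_PLANTS = (1, 2, 4, 5, 7, 8, 10)
DEFAULT_VAL_PLANTS = (3, 6, 9)


def split_by_plant(s: SpectraSet, cal_ids=DEFAULT_CAL_PLANTS, val_ids=DEFAULT_VAL_PLANTS):
    """Split spectra into calibration/validation sets by whole plants.

    No plant's spectra may straddle the two sets, and every plant present
    must be assigned to exactly one of them.
    """
    cal_ids, val_ids = set(cal_ids), set(val_ids)
    overlap = cal_ids & val_ids
    if overlap:
        raise ValueError(f"calibration and validation plant ids overlap: {sorted(overlap)}")
    present = set(s.meta["plant_id"].unique())
    orphan = present - cal_ids - val_ids
    if orphan:
        raise ValueError(f"plant id(s) {sorted(orphan)} assigned to neither set")
    if not val_ids & present:
        warnings.warn("validation set is empty: all plants assigned to calibration")
    cal = select_subset(s, plant_id=sorted(cal_ids))
    val = select_subset(s, plant_id=sorted(val_ids))
    return cal, val


@dataclasses.dataclass
class CvResult:
    """Leave-one-out cross-validation summary over candidate LV counts."""

    secv_by_lv: np.ndarray          # SECV for 1..max_lv latent variables
    rcv_by_lv: np.ndarray
    chosen_lv: int                  # first minimiser of SECV
    loo_predictions: np.ndarray     # n × max_lv

    @property
    def secv(self) -> float:
        return float(self.secv_by_lv[self.chosen_lv - 1])

    @property
    def rcv(self) -> float:
        return float(self.rcv_by_lv[self.chosen_lv - 1])


def loocv(X, y, max_lv: int, denominator: str = "n", **pls_kwargs) -> CvResult:
    """Leave-one-out cross-validation of :class:`NipalsPls`.

    For every sample i a model is refitted on the remaining n−1 samples
    and predicts sample i with 1..max_lv latent variables (the NIPALS
    coefficient path makes the nested models one fit per left-out sample).
    SECV is the root-mean-square LOO residual; ``denominator='n-1'``
    switches to an (n−1)-denominator convention.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    if max_lv > n - 2:
        raise ValueError(f"max_lv={max_lv} too large for n={n} (needs <= n-2)")
    if denominator not in ("n", "n-1"):
        raise ValueError("denominator must be 'n' or 'n-1'")
    preds = np.zeros((n, max_lv))
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        m = NipalsPls(n_components=max_lv, **pls_kwargs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(X[keep], y[keep])
        xi = X[i] - m.x_mean_
        preds[i] = xi @ m.coef_path_ + m.y_mean_
    resid = preds - y[:, None]
    denom = n if denominator == "n" else n - 1
    secv = np.sqrt((resid**2).sum(axis=0) / denom)
    rcv = np.array([_pearson(y, preds[:, k]) for k in range(max_lv)])
    chosen = int(np.argmin(secv)) + 1   # argmin takes the first minimum: parsimony
    return CvResult(secv, rcv, chosen, preds)


def _pearson(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def calibration_stats(model: NipalsPls, X, y, n_lv: int | None = None):
    """(SEC, Rcal): SEC uses the (n − n_lv − 1) denominator."""
    y = np.asarray(y, dtype=float).ravel()
    n_lv = model.n_components_ if n_lv is None else n_lv
    n = y.size
    if n <= n_lv + 1:
        raise ValueError(f"SEC undefined: n={n} <= n_lv+1={n_lv + 1}")
    yhat = model.predict(X, n_components=n_lv)
    rss = float(((y - yhat) ** 2).sum())
    sec = np.sqrt(rss / (n - n_lv - 1))
    return float(sec), _pearson(y, yhat)


def validation_stats(model: NipalsPls, X, y, n_lv: int | None = None):
    """(SEP, Rval): SEP is the RMS error on the untouched validation set."""
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("validation set is empty")
    yhat = model.predict(X, n_components=n_lv)
    sep = float(np.sqrt(np.mean((y - yhat) ** 2)))
    return sep, _pearson(y, yhat)
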