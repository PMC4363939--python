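"""Partial least squares regression via NIPALS, with missing-value support.

The estimator here is the modelling core of the package: a latent-variable
regression for the few-observations / many-genes regime, where expression of
hundreds of genes over a handful of diet-group observations predicts a late
physiological response.  The NIPALS algorithm is used because it tolerates
missing predictor entries natively (available-data projections), which the
union gene-list protocol requires — genes absent from one week's master list
enter the design matrix as missing.

Model quality is summarised by R2 (fraction of training variance explained)
and Q2 (fraction predicted under k-fold cross-validation); Q2 > 0.5 is the
conventional gate for a usefully predictive model.  Predictor influence is
ranked by VIP (variable importance in projection), whose squared values
average to 1, so VIP > 1 marks a variable with above-average influence.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin


__all__ = [
    "PLSNipals",
    "Diagnostics",
    "q2_score",
    "choose_components",
    "vip_scores",
    "select_and_refit",
]


@dataclass
class Diagnostics:
    """Fit and cross-validation summary for one PLS model.

    Attributes
    ----------
    r2x, r2y : float
        Fraction of (scaled) X / Y training variance explained, in [0, 1].
    q2 : float
        Cumulative cross-validated predictive fraction, 1 - PRESS/SS.
        May be negative for non-predictive models; bounded above by 1.
    q2_increments : list of float
        Marginal Q2 gained by each successive latent component.
    cv_folds, cv_seed : int
        Cross-validation configuration, recorded for reproducibility.
    """

    r2x: float
    r2y: float
    q2: float
    q2_increments: list = field(default_factory=list)
    cv_folds: int = 7
    cv_seed: int = 0
    n_components: int = 1

    def to_dict(self):
        return asdict(self)


def _as_2d(Y):
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    return Y


class PLSNipals(RegressorMixin, BaseEstimator):
    """PLS regression fitted by NIPALS, tolerating missing X entries.

    Parameters
    ----------
    n_components : int, default=2
        Number of latent components A.
    scale : bool, default=True
        Scale columns of X and Y to unit variance (ddof=1) after centering.
    max_iter : int, default=500
        Maximum NIPALS power iterations per component (multi-response only;
        single-response weights are closed-form).
    tol : float, default=1e-12
        Convergence tolerance on the change in the weight vector.

    Attributes
    ----------
    x_weights_ : ndarray (p, A)   unit-norm NIPALS weights W
    x_loadings_ : ndarray (p, A)  loadings P
    y_loadings_ : ndarray (r, A)  loadings Q
    x_scores_ : ndarray (n, A)    scores T (mutually orthogonal on
                                  complete data)
    coef_ : ndarray (p, r)        regression coefficients on the original
                                  scale; Yhat = X @ coef_ + intercept_
    intercept_ : ndarray (r,)
    y_ss_per_component_ : ndarray (A,)
        Explained Y sum of squares per component (scaled space); the
        weighting used by VIP.
    r2x_, r2y_ : float
    feature_names_in_ : ndarray of str, when X is a DataFrame.
    dropped_features_ : list of column identifiers removed for having zero
        variance.

    Notes
    -----
    Missing X entries (NaN) are handled by available-data projections in
    both fitting and prediction; a row with no observed entries predicts
    the training Y mean.  Score orthogonality is exact only on complete
    data.
    """

    def __init__(self, n_components=2, scale=True, max_iter=500, tol=1e-12):
        self.n_components = n_components
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol

    # ------------------------------------------------------------------ fit

    def fit(self, X, Y):
        X, feature_names = self._extract(X)
        Y = _as_2d(Y)
        n, p = X.shape
        if Y.shape[0] != n:
            raise ValueError(
                f"X has {n} rows but Y has {Y.shape[0]}"
            )
        if n < 2:
            raise ValueError("at least 2 observations are required")
        if np.isnan(Y).any():
            raise ValueError("Y must be fully observed for fitting")
        obs = ~np.isnan(X)
        if (~obs).all(axis=1).any():
            raise ValueError("X contains a row with no observed entries")
        if (~obs).all(axis=0).any():
            raise ValueError("X contains a column with no observed entries")

        # centering / scaling on available data
        x_mean = np.nanmean(X, axis=0)
        y_mean = Y.mean(axis=0)
        if self.scale:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                x_std = np.nanstd(X, axis=0, ddof=1)
            y_std = Y.std(axis=0, ddof=1)
            y_std = np.where(y_std <= 0, 1.0, y_std)
        else:
            x_std = np.ones(p)
            y_std = np.ones(Y.shape[1])

        keep = np.isfinite(x_std) & (x_std > 0)
        self.dropped_features_ = (
            [feature_names[j] for j in np.flatnonzero(~keep)]
            if feature_names is not None
            else list(np.flatnonzero(~keep))
        )
        if self.dropped_features_:
            warnings.warn(
                f"dropping {len(self.dropped_features_)} zero-variance "
                f"column(s): {self.dropped_features_[:5]}",
                stacklevel=2,
            )
        self._keep = keep
        Xw = X[:, keep]
        x_mean, x_std = x_mean[keep], x_std[keep]
        p_eff = Xw.shape[1]
        if p_eff == 0:
            raise ValueError("no usable (non-constant) predictor columns")

        A = int(self.n_components)
        A_max = min(n - 1, p_eff)
        if A < 1 or A > A_max:
            raise ValueError(
                f"n_components={A} out of range [1, {A_max}] for "
                f"{n} rows and {p_eff} usable columns"
            )

        Xc = (Xw - x_mean) / (x_std if self.scale else 1.0)
        Yc = (Y - y_mean) / y_std
        obs = ~np.isnan(Xc)
        Xc = np.where(obs, Xc, 0.0)  # zeros are ignored via the obs mask

        ssx_total = float(np.sum(Xc[obs] ** 2))
        ssy_total = float(np.sum(Yc**2))

        W = np.zeros((p_eff, A))
        P = np.zeros((p_eff, A))
        Q = np.zeros((Y.shape[1], A))
        T = np.zeros((n, A))
        ss_y = np.zeros(A)
        ss_x = np.zeros(A)

        Xd, Yd = Xc.copy(), Yc.copy()
        for a in range(A):
            w, t = self._nipals_component(Xd, Yd, obs)
            tt = float(t @ t)
            if tt <= np.finfo(float).eps:
                A = a
                break
            # loadings from available data
            denom = obs.T.astype(float) @ (t**2)
            denom = np.where(denom <= 0, 1.0, denom)
            p_a = (Xd * obs).T @ t / denom
            q_a = Yd.T @ t / tt
            Xd = Xd - np.where(obs, np.outer(t, p_a), 0.0)
            Yd = Yd - np.outer(t, q_a)
            W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_a, q_a, t
            ss_y[a] = float(q_a @ q_a) * tt
            ss_x[a] = float(p_a @ p_a) * tt

        if A == 0:
            raise ValueError("X has no variation; cannot extract a component")
        W, P, Q, T, ss_y, ss_x = (
            W[:, :A], P[:, :A], Q[:, :A], T[:, :A], ss_y[:A], ss_x[:A]
        )

        self.n_components_ = A
        self.x_weights_, self.x_loadings_ = W, P
        self.y_loadings_, self.x_scores_ = Q, T
        self.y_ss_per_component_ = ss_y
        self.r2x_ = float(ss_x.sum() / ssx_total) if ssx_total > 0 else 0.0
        self.r2y_ = float(ss_y.sum() / ssy_total) if ssy_total > 0 else 1.0
        self.x_mean_, self.x_std_ = x_mean, x_std
        self.y_mean_, self.y_std_ = y_mean, y_std
        self.feature_names_in_ = (
            np.asarray(feature_names) if feature_names is not None else None
        )
        # B in scaled space, then mapped to the original scale
        R = W @ np.linalg.pinv(P.T @ W)
        B_scaled = R @ Q.T
        self._rotations = R
        scale_x = self.x_std_ if self.scale else np.ones(p_eff)
        self.coef_ = (B_scaled / scale_x[:, None]) * self.y_std_[None, :]
        self.intercept_ = self.y_mean_ - self.x_mean_ @ self.coef_
        return self

    def _nipals_component(self, Xd, Yd, obs):
        """One NIPALS component on the (deflated) scaled matrices."""
        n, r = Yd.shape
        # start from the first Y column with appreciable variation
        norms = (Yd**2).sum(axis=0)
        u = Yd[:, int(np.argmax(norms > np.finfo(float).eps * norms.max()))
               if norms.max() > 0 else 0].copy()
        if not u.any():
            u = Yd[:, 0].copy()
        w_old = None
        for _ in range(self.max_iter):
            denom = obs.T.astype(float) @ (u**2)
            denom = np.where(denom <= 0, 1.0, denom)
            w = (Xd * obs).T @ u / denom
            nw = np.linalg.norm(w)
            if nw <= np.finfo(float).eps:
                w = np.zeros_like(w)
                return w, np.zeros(n)
            w /= nw
            row_denom = obs.astype(float) @ (w**2)
            t = np.where(row_denom > 0, (Xd * obs) @ w / np.where(
                row_denom > 0, row_denom, 1.0), 0.0)
            tt = float(t @ t)
            if tt <= np.finfo(float).eps:
                return w, t
            q = Yd.T @ t / tt
            qq = float(q @ q)
            u = Yd @ q / (qq if qq > 0 else 1.0)
            if r == 1:
                break
            if w_old is not None and np.linalg.norm(w - w_old) < self.tol:
                break
            w_old = w
        return w, t

    # -------------------------------------------------------------- predict

    def _extract(self, X):
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), list(map(str, X.columns))
        return np.asarray(X, dtype=float), None

    def _check_columns(self, X, names):
        if names is not None and self.feature_names_in_ is not None:
            trained = list(self.feature_names_in_)
            unknown = [c for c in names if c not in set(trained)]
            if unknown:
                raise ValueError(f"unknown predictor column(s): {unknown}")
            if names != trained:
                # reorder / subset to the training layout; absent → missing
                frame = pd.DataFrame(X, columns=names)
                frame = frame.reindex(columns=trained)
                X = frame.to_numpy(dtype=float)
        return X

    def predict(self, X, n_components=None):
        """Predict responses on the original scale.

        Missing entries contribute through available-data score estimation;
        a fully missing row yields the training Y mean.  ``n_components``
        truncates the model to its first components (used by
        cross-validation).
        """
        if not hasattr(self, "coef_"):
            raise ValueError("model is not fitted")
        X, names = self._extract(X)
        if X.ndim == 1:
            X = X[None, :]
        X = self._check_columns(X, names)
        if X.shape[1] == self._keep.size:
            X = X[:, self._keep]
        if X.shape[1] != self.x_mean_.size:
            raise ValueError(
                f"X has {X.shape[1]} columns; the model expects "
                f"{self._keep.size} (or {self.x_mean_.size} after the "
                "zero-variance drop)"
            )
        A = self.n_components_ if n_components is None else int(n_components)
        if A < 1 or A > self.n_components_:
            raise ValueError(f"n_components must be in [1, {self.n_components_}]")

        Xc = (X - self.x_mean_) / (self.x_std_ if self.scale else 1.0)
        obs = ~np.isnan(Xc)
        Xd = np.where(obs, Xc, 0.0)
        T = np.zeros((X.shape[0], A))
        for a in range(A):
            w = self.x_weights_[:, a]
            denom = obs.astype(float) @ (w**2)
            t = np.where(denom > 0, Xd @ w / np.where(denom > 0, denom, 1.0), 0.0)
            Xd = Xd - np.where(obs, np.outer(t, self.x_loadings_[:, a]), 0.0)
            T[:, a] = t
        Yhat = T @ self.y_loadings_[:, :A].T
        return Yhat * self.y_std_ + self.y_mean_

    def fitted_values(self):
        """Training-set predictions implied by the stored scores."""
        Yhat = self.x_scores_ @ self.y_loadings_.T
        return Yhat * self.y_std_ + self.y_mean_

    # ------------------------------------------------------- serialization

    def to_json(self) -> str:
        """Serialize the fitted model to a JSON document."""
        if not hasattr(self, "coef_"):
            raise ValueError("model is not fitted")
        doc = {
            "params": self.get_params(),
            "n_components_": int(self.n_components_),
            "x_weights_": self.x_weights_.tolist(),
            "x_loadings_": self.x_loadings_.tolist(),
            "y_loadings_": self.y_loadings_.tolist(),
            "x_scores_": self.x_scores_.tolist(),
            "y_ss_per_component_": self.y_ss_per_component_.tolist(),
            "x_mean_": self.x_mean_.tolist(),
            "x_std_": self.x_std_.tolist(),
            "y_mean_": self.y_mean_.tolist(),
            "y_std_": self.y_std_.tolist(),
            "coef_": self.coef_.tolist(),
            "intercept_": self.intercept_.tolist(),
            "r2x_": self.r2x_,
            "r2y_": self.r2y_,
            "keep": self._keep.tolist(),
            "feature_names_in_": (
                None
                if self.feature_names_in_ is None
                else list(map(str, self.feature_names_in_))
            ),
            "dropped_features_": [str(d) for d in self.dropped_features_],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, doc: str) -> "PLSNipals":
        d = json.loads(doc)
        model = cls(**d["params"])
        model.n_components_ = d["n_components_"]
        for key in (
            "x_weights_", "x_loadings_", "y_loadings_", "x_scores_",
            "y_ss_per_component_", "x_mean_", "x_std_", "y_mean_", "y_std_",
            "coef_", "intercept_",
        ):
            setattr(model, key, np.asarray(d[key], dtype=float))
        model.r2x_, model.r2y_ = d["r2x_"], d["r2y_"]
        model._keep = np.asarray(d["keep"], dtype=bool)
        model.feature_names_in_ = (
            None
            if d["feature_names_in_"] is None
            else np.asarray(d["feature_names_in_"])
        )
        model.dropped_features_ = d["dropped_features_"]
        model._rotations = model.x_weights_ @ np.linalg.pinv(
            model.x_loadings_.T @ model.x_weights_
        )
        return model


# ---------------------------------------------------------------------------
# Cross-validated Q2 and component selection
# ---------------------------------------------------------------------------


def _fold_assignment(n: int, folds: int, seed: int) -> np.ndarray:
    """Deterministic round-robin fold ids after a seeded shuffle."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_id = np.empty(n, dtype=int)
    fold_id[perm] = np.arange(n) % folds
    return fold_id


def q2_score(X, Y, n_components, folds=7, seed=0, scale=True) -> Diagnostics:
    """Cumulative cross-validated Q2 = 1 - PRESS/SS, per component.

    Rows are assigned to ``folds`` groups round-robin after a seeded
    shuffle; each fold is predicted by a model trained on the rest.  PRESS
    and the total sum of squares are computed on Y scaled to unit column
    variance of the full data, so multi-response panels weigh each response
    equally.
    """
    Xarr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    Yarr = _as_2d(Y)
    n = Xarr.shape[0]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > n:
        raise ValueError(f"folds={folds} exceeds the {n} observations")
    A = int(n_components)

    y_mean = Yarr.mean(axis=0)
    y_sd = Yarr.std(axis=0, ddof=1) if scale else np.ones(Yarr.shape[1])
    y_sd = np.where(y_sd <= 0, 1.0, y_sd)
    ss = float((((Yarr - y_mean) / y_sd) ** 2).sum())

    fold_id = _fold_assignment(n, folds, seed)
    press = np.zeros(A)
    for k in range(folds):
        test = fold_id == k
        train = ~test
        model = PLSNipals(
            n_components=min(A, train.sum() - 1, Xarr.shape[1]), scale=scale
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X[train] if isinstance(X, pd.DataFrame) else Xarr[train],
                      Yarr[train])
        for a in range(1, A + 1):
            a_eff = min(a, model.n_components_)
            pred = model.predict(
                X[test] if isinstance(X, pd.DataFrame) else Xarr[test],
                n_components=a_eff,
            )
            press[a - 1] += float((((Yarr[test] - pred) / y_sd) ** 2).sum())

    q2_cum = 1.0 - press / ss if ss > 0 else np.zeros(A)
    increments = np.diff(np.concatenate([[0.0], q2_cum])).tolist()

    full = PLSNipals(n_components=A, scale=scale)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full.fit(X, Yarr)
    return Diagnostics(
        r2x=full.r2x_,
        r2y=full.r2y_,
        q2=float(q2_cum[-1]),
        q2_increments=increments,
        cv_folds=folds,
        cv_seed=seed,
        n_components=A,
    )


def choose_components(
    X,
    Y,
    folds=7,
    seed=0,
    max_components=10,
    min_increment=0.01,
    scale=True,
):
    """Smallest adequate component count by the marginal-Q2 rule.

    Components are added while each one's marginal Q2 gain exceeds
    ``min_increment``, capped at min(n-1, p, max_components).  Always
    returns at least 1, and never a component count whose last increment
    is negative.
    """
    Xarr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    n, p = Xarr.shape
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p_eff = int((np.nanstd(Xarr, axis=0, ddof=1) > 0).sum())
    cap = max(1, min(n - 1, p_eff, max_components))
    probe = q2_score(X, Y, n_components=cap, folds=folds, seed=seed, scale=scale)
    a = 1
    while a < cap and probe.q2_increments[a] > min_increment:
        a += 1
    # diagnostics at the chosen size: cumulative Q2 is the prefix sum of
    # the per-component increments already measured fold-wise
    full = PLSNipals(n_components=a, scale=scale)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full.fit(X, _as_2d(Y))
    diag = Diagnostics(
        r2x=full.r2x_,
        r2y=full.r2y_,
        q2=float(np.sum(probe.q2_increments[:a])),
        q2_increments=probe.q2_increments[:a],
        cv_folds=folds,
        cv_seed=seed,
        n_components=a,
    )
    return a, diag


# ---------------------------------------------------------------------------
# VIP and selection
# ---------------------------------------------------------------------------


def vip_scores(model: PLSNipals):
    """Variable importance in projection for a fitted model.

    VIP_j = sqrt( p * sum_a SS_a (w_aj/||w_a||)^2 / sum_a SS_a ) where SS_a
    is the Y sum of squares explained by component a.  Squared VIPs average
    to 1 over the p predictors.  Returns a pandas Series indexed by feature
    name when available.
    """
    if not hasattr(model, "x_weights_"):
        raise ValueError("model is not fitted")
    W = model.x_weights_
    ss = model.y_ss_per_component_
    p = W.shape[0]
    wnorm2 = (W**2).sum(axis=0)
    wnorm2 = np.where(wnorm2 <= 0, 1.0, wnorm2)
    vip = np.sqrt(p * ((W**2 / wnorm2) @ ss) / ss.sum())
    if model.feature_names_in_ is not None:
        kept = np.asarray(model.feature_names_in_)[model._keep]
        return pd.Series(vip, index=kept, name="VIP")
    return pd.Series(vip, name="VIP")


def select_and_refit(
    X,
    Y,
    n_components=None,
    cutoff=1.0,
    folds=7,
    seed=0,
    scale=True,
):
    """VIP-threshold variable selection followed by a refit.

    Fits a full model (component count chosen by the marginal-Q2 rule when
    ``n_components`` is None), keeps predictors with VIP > ``cutoff``,
    refits on the reduced matrix, and reports both models' diagnostics.

    Returns
    -------
    selected : list
        Names (or indices) of the retained predictors.
    refit : PLSNipals
        Model refitted on the selected predictors.
    diagnostics : dict
        ``{"full": Diagnostics, "selected": Diagnostics}``.
    """
    if n_components is None:
        A, diag_full = choose_components(X, Y, folds=folds, seed=seed, scale=scale)
    else:
        A = int(n_components)
        diag_full = q2_score(X, Y, A, folds=folds, seed=seed, scale=scale)
    full = PLSNipals(n_components=A, scale=scale)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full.fit(X, Y)
    vip = vip_scores(full)
    mask = vip.to_numpy() > cutoff
    if not mask.any():
        raise ValueError(
            f"no variable has VIP above cutoff {cutoff}; the maximum is "
            f"{float(vip.max()):.4f} — try a lower cutoff"
        )
    if isinstance(X, pd.DataFrame):
        selected = list(vip.index[mask])
        X_sel = X.loc[:, selected]
    else:
        kept_idx = np.flatnonzero(full._keep)
        selected = list(kept_idx[mask])
        X_sel = np.asarray(X, float)[:, selected]

    A_sel, diag_sel = choose_components(
        X_sel, Y, folds=folds, seed=seed, scale=scale
    )
    refit = PLSNipals(n_components=A_sel, scale=scale)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        refit.fit(X_sel, Y)
    return selected, refit, {"full": diag_full, "selected": diag_sel}
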