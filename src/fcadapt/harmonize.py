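"""Parametric empirical-Bayes ComBat harmonization of feature matrices.

ComBat models each feature y_{ijg} (subject j, batch/site i, feature g)
as

    y_{ijg} = alpha_g + X_j beta_g + gamma_{ig} + delta_{ig} eps_{ijg}

with additive batch effects gamma and multiplicative effects delta on
the residual scale.  Features are first standardized by the grand
location, preserved-covariate effects and pooled scale; per-batch
location/scale estimates are then shrunk toward a common prior
(normal on gamma, inverse-gamma on delta^2) by empirical Bayes, and the
shrunken effects are removed before back-transforming.  Covariates one
wants to keep (e.g. diagnosis one-hots, age) are re-added, so the
biological signal is not scrubbed along with the site effect.

Implemented as a scikit-learn transformer so it composes with
pipelines: fit on training subjects, transform anything from the same
batches.  Transforming data from a batch unseen at fit time raises (no
extrapolation).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["ComBat", "fit_combat", "apply_combat"]


class ComBat(TransformerMixin, BaseEstimator):
    """Empirical-Bayes batch-effect harmonizer.

    Parameters
    ----------
    parametric : bool
        If True (default), shrink per-batch location/scale estimates via
        parametric empirical Bayes (normal prior on gamma, inverse-gamma
        on delta^2), iterated to convergence.  If False, use the raw
        per-batch moment estimates (no shrinkage).
    eb_tol, eb_max_iter : float, int
        Convergence tolerance (max absolute change of gamma*, delta*)
        and iteration cap of the EB fixed point.
    allow_single_batch : bool
        A single batch makes harmonization vacuous; by default fit
        raises with an advisory.  With this flag a degenerate identity
        model (gamma*=0, delta*=1) is fitted instead so transform
        returns its input unchanged.

    Fitted attributes
    -----------------
    batches_ : list of batch identifiers seen at fit.
    grand_mean_ : (n_features,) grand location alpha_g.
    beta_ : (n_covariates, n_features) preserved-covariate coefficients.
    pooled_var_ : (n_features,) pooled residual variance sigma_g^2.
    gamma_star_, delta_star_ : (n_batches, n_features) EB-shrunken
        additive effects and multiplicative (scale, not variance)
        effects; delta_star_ strictly positive.
    excluded_features_ : indices of zero-variance features passed
        through unchanged.
    """

    def __init__(self, parametric: bool = True, eb_tol: float = 1e-6,
                 eb_max_iter: int = 100, allow_single_batch: bool = False):
        self.parametric = parametric
        self.eb_tol = eb_tol
        self.eb_max_iter = eb_max_iter
        self.allow_single_batch = allow_single_batch

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y=None, *, batch, covariates=None):
        """Estimate the harmonization model.

        Parameters
        ----------
        X : (n_subjects, n_features)
        batch : length-n array of batch (site) identifiers.
        covariates : optional (n_subjects, n_covariates) design of
            effects to preserve (already encoded numerically).
        """
        X = np.asarray(X, dtype=np.float64)
        batch = np.asarray(batch)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (subjects x features)")
        n, p = X.shape
        if len(batch) != n:
            raise ValueError("batch length does not match X")
        self.batches_ = sorted(set(batch.tolist()))
        if len(self.batches_) < 2 and not self.allow_single_batch:
            raise ValueError(
                "only one batch present: harmonization is vacuous; pass "
                "allow_single_batch=True for an identity model"
            )
        counts = {b: int((batch == b).sum()) for b in self.batches_}
        if min(counts.values()) < 2:
            raise ValueError("every batch needs at least 2 subjects to fit")

        C = None
        if covariates is not None:
            C = np.asarray(covariates, dtype=np.float64)
            if C.ndim == 1:
                C = C[:, None]
            # center so covariates do not absorb the grand mean
            self._cov_center_ = C.mean(axis=0)
            C = C - self._cov_center_
        else:
            self._cov_center_ = None
        self.n_covariates_ = 0 if C is None else C.shape[1]

        constant = np.ptp(X, axis=0) == 0
        self.excluded_features_ = np.flatnonzero(constant)
        active = np.flatnonzero(~constant)
        if self.excluded_features_.size:
            import warnings

            warnings.warn(
                f"{self.excluded_features_.size} zero-variance feature(s) "
                "excluded from harmonization and passed through unchanged",
                RuntimeWarning,
                stacklevel=2,
            )
        Xa = X[:, active]

        # one-hot batch design + centered covariates
        K = len(self.batches_)
        B = np.zeros((n, K))
        for k, b in enumerate(self.batches_):
            B[batch == b, k] = 1.0
        design = B if C is None else np.hstack([B, C])
        coef, *_ = np.linalg.lstsq(design, Xa, rcond=None)
        gamma_hat_ols = coef[:K]                       # per-batch means
        beta = coef[K:]                                # covariate effects
        w = np.array([counts[b] for b in self.batches_], dtype=float) / n
        alpha = w @ gamma_hat_ols                      # weighted grand mean

        fitted = design @ coef
        resid = Xa - fitted
        pooled_var = (resid**2).mean(axis=0)
        pooled_var = np.maximum(pooled_var, 1e-12)

        stand_mean = alpha[None, :] + (0 if C is None else C @ beta)
        Z = (Xa - stand_mean) / np.sqrt(pooled_var)

        gamma_hat = np.empty((K, Xa.shape[1]))
        delta2_hat = np.empty((K, Xa.shape[1]))
        for k, b in enumerate(self.batches_):
            zb = Z[batch == b]
            gamma_hat[k] = zb.mean(axis=0)
            delta2_hat[k] = zb.var(axis=0, ddof=1)
        delta2_hat = np.maximum(delta2_hat, 1e-12)

        if len(self.batches_) == 1:
            gamma_star = np.zeros_like(gamma_hat)
            delta2_star = np.ones_like(delta2_hat)
        elif self.parametric:
            gamma_star, delta2_star = self._eb_shrink(
                Z, batch, gamma_hat, delta2_hat, counts
            )
        else:
            gamma_star, delta2_star = gamma_hat, delta2_hat

        self.grand_mean_ = np.zeros(p)
        self.grand_mean_[active] = alpha
        self.beta_ = np.zeros((self.n_covariates_, p))
        if self.n_covariates_:
            self.beta_[:, active] = beta
        self.pooled_var_ = np.ones(p)
        self.pooled_var_[active] = pooled_var
        self.gamma_star_ = np.zeros((K, p))
        self.gamma_star_[:, active] = gamma_star
        self.delta_star_ = np.ones((K, p))
        self.delta_star_[:, active] = np.sqrt(delta2_star)
        self._active_ = active
        self.n_features_in_ = p
        return self

    def _eb_shrink(self, Z, batch, gamma_hat, delta2_hat, counts):
        """Parametric EB fixed point (normal / inverse-gamma priors)."""
        K, p = gamma_hat.shape
        gamma_bar = gamma_hat.mean(axis=1, keepdims=True)     # per batch
        tau2 = gamma_hat.var(axis=1, ddof=1, keepdims=True)
        tau2 = np.maximum(tau2, 1e-12)
        # inverse-gamma prior on delta^2, moment-matched across features
        v = delta2_hat.mean(axis=1, keepdims=True)
        s2 = delta2_hat.var(axis=1, ddof=1, keepdims=True)
        s2 = np.maximum(s2, 1e-12)
        lam = (2 * s2 + v**2) / s2                            # shape
        theta = (v**3 + v * s2) / s2                          # scale

        gamma_star = gamma_hat.copy()
        delta2_star = delta2_hat.copy()
        n_k = np.array([counts[b] for b in self.batches_], dtype=float)[:, None]
        masks = [np.asarray(batch) == b for b in self.batches_]
        sum_sq = np.empty_like(gamma_hat)
        for it in range(self.eb_max_iter):
            g_new = (n_k * tau2 * gamma_hat + delta2_star * gamma_bar) / (
                n_k * tau2 + delta2_star
            )
            for k, m in enumerate(masks):
                sum_sq[k] = ((Z[m] - g_new[k]) ** 2).sum(axis=0)
            d_new = (theta + 0.5 * sum_sq) / (n_k / 2.0 + lam - 1.0)
            d_new = np.maximum(d_new, 1e-12)
            change = max(
                np.abs(g_new - gamma_star).max(), np.abs(d_new - delta2_star).max()
            )
            gamma_star, delta2_star = g_new, d_new
            if change < self.eb_tol:
                break
        return gamma_star, delta2_star

    # -- application -----------------------------------------------------
    def transform(self, X, *, batch, covariates=None):
        """Remove batch effects; preserved-covariate effects are restored."""
        check_is_fitted(self, "gamma_star_")
        X = np.asarray(X, dtype=np.float64)
        batch = np.asarray(batch)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        unseen = set(batch.tolist()) - set(self.batches_)
        if unseen:
            raise ValueError(f"batch(es) {sorted(unseen)} not seen at fit time")
        C = None
        if self.n_covariates_:
            if covariates is None:
                raise ValueError("model was fitted with covariates; pass them")
            C = np.asarray(covariates, dtype=np.float64)
            if C.ndim == 1:
                C = C[:, None]
            C = C - self._cov_center_
        a = self._active_
        stand_mean = self.grand_mean_[a][None, :] + (
            0 if C is None else C @ self.beta_[:, a]
        )
        sigma = np.sqrt(self.pooled_var_[a])
        Z = (X[:, a] - stand_mean) / sigma
        out = X.copy()
        idx = {b: k for k, b in enumerate(self.batches_)}
        for b in set(batch.tolist()):
            m = batch == b
            k = idx[b]
            adj = (Z[m] - self.gamma_star_[k, a]) / self.delta_star_[k, a]
            out[np.ix_(m, a)] = adj * sigma + (
                stand_mean[m] if C is not None else stand_mean
            )
        return out

    def fit_transform(self, X, y=None, *, batch, covariates=None):
        return self.fit(X, batch=batch, covariates=covariates).transform(
            X, batch=batch, covariates=covariates
        )


def fit_combat(features, batch, covariates=None, parametric: bool = True,
               **kwargs) -> ComBat:
    """Functional wrapper: fit a :class:`ComBat` model."""
    return ComBat(parametric=parametric, **kwargs).fit(
        features, batch=batch, covariates=covariates
    )


def apply_combat(model: ComBat, features, batch, covariates=None) -> np.ndarray:
    """Functional wrapper: apply a fitted :class:`ComBat` model."""
    return model.transform(features, batch=batch, covariates=covariates)
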