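"""Whole-genome linear regressions.

Two families live here:

* :func:`fit_ridge_blup` — ridge regression BLUP: all marker effects shrunk
  uniformly, with the penalty ``lambda = sigma2_e / sigma2_b`` estimated from
  the data by restricted maximum likelihood (REML) on the equivalent
  single-variance-component random-effects model.
* :func:`fit_bayesian_regression` — single-site Gibbs samplers for Bayesian
  ridge regression (BRR, one common marker variance), BayesA (per-marker
  scaled-inverse-chi^2 variances), BayesB (BayesA plus a point mass at zero
  with probability ``pi_zero``) and the Bayesian LASSO (double-exponential
  shrinkage via the normal-exponential mixture of Park & Casella).

Prior scales follow the convention that the prior proportion of phenotypic
variance explained by markers is ``r2`` (default 0.5): with ``MSx`` the sum
of marker variances, the marker-variance prior mode is set to
``var(y) * r2 / MSx`` (divided by ``1 - pi_zero`` for BayesB so the markers
that are "in" still account for ``r2``), and the residual prior mode to
``var(y) * (1 - r2)``.  The Bayesian LASSO rate is initialized at
``lambda^2 = 2 * MSx * (1 - r2) / r2`` and updated with a Gamma step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import linalg, optimize

from .datatypes import AlignmentError, DegenerateTraitError, GenotypeMatrix

__all__ = [
    "BayesPrior",
    "LinearModelFit",
    "SamplerError",
    "ridge_solve",
    "fit_ridge_blup",
    "fit_bayesian_regression",
    "predict_linear",
    "BAYES_MODELS",
]

BAYES_MODELS = ("BRR", "BA", "BB", "BL")


class SamplerError(RuntimeError):
    """The Gibbs chain reached a non-finite state."""


@dataclass
class BayesPrior:
    """Hyperparameters for the Bayesian regressions.

    ``df`` is the degrees of freedom of the scaled-inverse-chi^2 priors on
    marker and residual variances; ``r2`` the prior proportion of variance
    explained used to elicit the scales; ``pi_zero`` the BayesB prior
    probability that a marker effect is exactly zero; ``scale`` overrides the
    elicited marker-variance scale when given.
    """

    df: float = 5.0
    r2: float = 0.5
    pi_zero: float = 0.95
    scale: float | None = None
    update_pi: bool = False  # Beta-updated pi_zero variant

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValueError("df must be > 0")
        if not (0.0 < self.r2 < 1.0):
            raise ValueError("r2 must be in (0, 1)")
        if not (0.0 <= self.pi_zero <= 1.0):
            raise ValueError("pi_zero must be in [0, 1]")


@dataclass
class LinearModelFit:
    """A trained whole-genome linear predictor.

    ``marker_effects`` are posterior means for the Bayesian fits and BLUPs
    for ridge; ``effect_sd`` the posterior standard deviations (Bayesian
    only).  ``fitted_values`` are in-sample predictions on the training
    lines, recorded at fit time.
    """

    algorithm: str
    intercept: float
    marker_effects: np.ndarray
    sigma2_e: float
    sigma2_b: float | np.ndarray | None = None
    lambda_: float | None = None
    marker_ids: list[str] | None = None
    effect_sd: np.ndarray | None = None
    iterations: int | None = None
    burn_in: int | None = None
    fitted_values: np.ndarray | None = None
    diagnostics: dict[str, Any] = field(default_factory=dict)

    @property
    def marker_scores(self) -> np.ndarray:
        """Per-marker scores for ranking / network seeding (signed effects)."""
        return self.marker_effects

    def to_dict(self) -> dict[str, Any]:
        """JSON-serializable summary of the fit."""
        return {
            "algorithm": self.algorithm,
            "intercept": float(self.intercept),
            "marker_effects": np.asarray(self.marker_effects).tolist(),
            "sigma2_e": float(self.sigma2_e),
            "sigma2_b": None
            if self.sigma2_b is None
            else np.asarray(self.sigma2_b).tolist(),
            "lambda": None if self.lambda_ is None else float(self.lambda_),
            "iterations": self.iterations,
            "burn_in": self.burn_in,
        }


def _as_X(G) -> np.ndarray:
    if isinstance(G, GenotypeMatrix):
        return np.asfortranarray(G.X())
    return np.asfortranarray(np.asarray(G, dtype=float))


def _marker_ids(G) -> list[str] | None:
    return list(G.marker_ids) if isinstance(G, GenotypeMatrix) else None


def ridge_solve(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form ridge coefficients ``(X'X + lam I)^-1 X'y``.

    Uses the dual form ``X'(XX' + lam I)^-1 y`` when p > n.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p <= n:
        A = X.T @ X + lam * np.eye(p)
        return linalg.solve(A, X.T @ y, assume_a="pos")
    A = X @ X.T + lam * np.eye(n)
    return X.T @ linalg.solve(A, y, assume_a="pos")


def fit_ridge_blup(
    G_train,
    y_train: np.ndarray,
    lambda_: float | None = None,
) -> LinearModelFit:
    """Ridge-BLUP with a REML-estimated penalty.

    The model is ``y = mu + X b + e`` with ``b ~ N(0, sigma2_b I)`` and
    ``e ~ N(0, sigma2_e I)``; the variance ratio ``delta = sigma2_e /
    sigma2_b`` is found by maximizing the restricted likelihood on the
    spectrum of the marker kernel ``K = XX'`` (one-dimensional search,
    tolerance 1e-6 on the ratio).  Pass ``lambda_`` to skip REML and fit at a
    fixed penalty.  Deterministic given the input.

    A constant response returns a zero-effect fit with the constant as
    intercept.
    """
    X = _as_X(G_train)
    y = np.asarray(y_train, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 training lines")
    if y.shape != (n,):
        raise AlignmentError("y_train length does not match G_train rows")

    if np.ptp(y) == 0.0:
        # zero-variance response: ridge solution is exactly zero effects
        return LinearModelFit(
            algorithm="rrBLUP",
            intercept=float(y[0]),
            marker_effects=np.zeros(p),
            sigma2_e=0.0,
            sigma2_b=0.0,
            lambda_=np.inf,
            marker_ids=_marker_ids(G_train),
            fitted_values=np.full(n, float(y[0])),
        )

    if lambda_ is None:
        # REML on the n-1 dimensional contrast space orthogonal to the mean
        K = X @ X.T
        # orthonormal basis of the complement of the intercept column
        T = linalg.null_space(np.ones((1, n)))  # (n, n-1)
        M = T.T @ K @ T
        xi, U = linalg.eigh(M)
        xi = np.clip(xi, 0.0, None)
        eta = U.T @ (T.T @ y)

        def neg_restricted_loglik(log_delta: float) -> float:
            d = np.exp(log_delta)
            w = xi + d
            return 0.5 * ((n - 1) * np.log(np.sum(eta**2 / w)) + np.sum(np.log(w)))

        res = optimize.minimize_scalar(
            neg_restricted_loglik,
            bounds=(np.log(1e-8), np.log(1e8)),
            method="bounded",
            options={"xatol": 1e-9},
        )
        delta = float(np.exp(res.x))
        sigma2_b = float(np.sum(eta**2 / (xi + delta)) / (n - 1))
        sigma2_e = delta * sigma2_b
    else:
        delta = float(lambda_)
        sigma2_b, sigma2_e = np.nan, np.nan

    # GLS intercept and BLUP effects at the chosen ratio
    H = X @ X.T + delta * np.eye(n)
    ones = np.ones(n)
    Hinv_y = linalg.solve(H, y, assume_a="pos")
    Hinv_1 = linalg.solve(H, ones, assume_a="pos")
    mu = float(ones @ Hinv_y / (ones @ Hinv_1))
    b = X.T @ linalg.solve(H, y - mu * ones, assume_a="pos")

    fit = LinearModelFit(
        algorithm="rrBLUP",
        intercept=mu,
        marker_effects=b,
        sigma2_e=float(sigma2_e),
        sigma2_b=float(sigma2_b),
        lambda_=delta,
        marker_ids=_marker_ids(G_train),
    )
    fit.fitted_values = predict_linear(fit, G_train)
    return fit


def _rinvgauss(
    rng: np.random.Generator, mu: np.ndarray, lam: float
) -> np.ndarray:
    """Vectorized inverse-Gaussian draws (Michael, Schucany & Haas)."""
    nu = rng.normal(size=mu.shape)
    w = nu * nu
    x = mu + mu * mu * w / (2.0 * lam) - (mu / (2.0 * lam)) * np.sqrt(
        4.0 * lam * mu * w + (mu * w) ** 2
    )
    x = np.maximum(x, 1e-12)
    z = rng.random(mu.shape)
    return np.where(z <= mu / (mu + x), x, mu * mu / x)


def fit_bayesian_regression(
    G_train,
    y_train: np.ndarray,
    model: str,
    iterations: int = 12_000,
    burn_in: int = 2_000,
    prior: BayesPrior | None = None,
    seed: int | None = None,
    fixed_variances: tuple[float, float] | None = None,
) -> LinearModelFit:
    """Gibbs-sampler posterior means for one of BRR / BA / BB / BL.

    The chain runs ``iterations`` sweeps and discards the first ``burn_in``;
    no thinning (all post-burn-in samples contribute to the posterior
    means).  Fixed ``seed`` gives a reproducible chain.  Convergence is
    summarized (not enforced) by a split-chain potential-scale-reduction
    statistic on ``sigma2_e``.

    ``fixed_variances=(sigma2_e, sigma2_b)`` freezes the variance components
    (BRR only), reducing the sampler to its conjugate-normal core — the
    posterior mean is then the closed-form ridge solution with
    ``lambda = sigma2_e / sigma2_b``, which serves as an external oracle.
    """
    if model not in BAYES_MODELS:
        raise ValueError(f"model must be one of {BAYES_MODELS}")
    if iterations <= burn_in:
        raise ValueError("iterations must exceed burn_in")
    prior = prior or BayesPrior()
    X = _as_X(G_train)
    y = np.asarray(y_train, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 training lines")
    if y.shape != (n,):
        raise AlignmentError("y_train length does not match G_train rows")
    if np.ptp(y) == 0.0:
        raise DegenerateTraitError("constant response; nothing to regress on")
    if fixed_variances is not None and model != "BRR":
        raise ValueError("fixed_variances is only supported for BRR")

    rng = np.random.default_rng(seed)
    vy = float(np.var(y))
    xtx = np.einsum("ij,ij->j", X, X)
    msx = float(np.sum(np.var(X, axis=0)))
    if msx == 0.0:
        raise DegenerateTraitError("all markers are monomorphic")

    df = prior.df
    df_e = prior.df
    S_e = vy * (1.0 - prior.r2) * (df_e + 2.0)
    pi_zero = prior.pi_zero
    if model == "BB" and pi_zero >= 1.0:
        raise ValueError("pi_zero must be < 1 for BayesB")
    frac_in = 1.0 if model != "BB" else (1.0 - pi_zero)
    if prior.scale is not None:
        S_b = prior.scale
    else:
        S_b = vy * prior.r2 / (msx * max(frac_in, 1e-3)) * (df + 2.0)

    # state
    mu = float(np.mean(y))
    b = np.zeros(p)
    e = y - mu
    s2e = S_e / (df_e + 2.0)
    if fixed_variances is not None:
        s2e = float(fixed_variances[0])
    s2b_common = S_b / (df + 2.0)  # BRR
    s2b = np.full(p, S_b / (df + 2.0))  # BA / BB per-marker
    included = np.ones(p, dtype=bool)
    lam2 = 2.0 * msx * (1.0 - prior.r2) / prior.r2  # BL
    lam_shape0, lam_rate0 = 1.1, 1.1 / lam2
    tau2 = np.full(p, 2.0 / lam2)

    n_keep = iterations - burn_in
    sum_mu = 0.0
    sum_b = np.zeros(p)
    sum_b2 = np.zeros(p)
    sum_s2e = 0.0
    sum_s2b = np.zeros(p) if model in ("BA", "BB") else 0.0
    sum_incl = np.zeros(p)
    s2e_chain = np.empty(n_keep)
    log_odds_prior = (
        np.log((1.0 - pi_zero) / pi_zero) if model == "BB" and pi_zero > 0 else np.inf
    )

    cols = [np.ascontiguousarray(X[:, j]) for j in range(p)]

    for it in range(iterations):
        # intercept
        mu_new = mu + np.mean(e) + rng.normal() * np.sqrt(s2e / n)
        e -= mu_new - mu
        mu = mu_new

        z = rng.normal(size=p)  # one Gaussian per marker, drawn up front
        u = rng.random(p) if model == "BB" else None

        for j in range(p):
            xj = cols[j]
            bj = b[j]
            rhs = xj @ e + xtx[j] * bj
            if model == "BRR":
                prec = xtx[j] + s2e / s2b_common
            elif model == "BL":
                prec = xtx[j] + 1.0 / tau2[j]
            else:
                prec = xtx[j] + s2e / s2b[j]

            if model == "BB" and pi_zero > 0.0:
                v_in = xtx[j] * s2b[j] + s2e
                log_bf = -0.5 * np.log(v_in / s2e) + 0.5 * rhs * rhs * s2b[j] / (
                    s2e * v_in
                )
                lo = log_odds_prior + log_bf
                p_in = 1.0 / (1.0 + np.exp(-lo)) if lo < 35 else 1.0
                if u[j] < p_in:
                    included[j] = True
                    bnew = rhs / prec + z[j] * np.sqrt(s2e / prec)
                else:
                    included[j] = False
                    bnew = 0.0
            else:
                bnew = rhs / prec + z[j] * np.sqrt(s2e / prec)
            if bnew != bj:
                e -= xj * (bnew - bj)
                b[j] = bnew

        # variance updates
        if model == "BRR":
            if fixed_variances is not None:
                s2e, s2b_common = fixed_variances
            else:
                s2b_common = (S_b + np.sum(b * b)) / rng.chisquare(df + p)
                s2e = (S_e + e @ e) / rng.chisquare(df_e + n)
        elif model in ("BA", "BB"):
            active = included if model == "BB" else np.ones(p, dtype=bool)
            chi_act = rng.chisquare(df + 1.0, size=p)
            chi_pri = rng.chisquare(df, size=p)
            s2b = np.where(
                active, (S_b + b * b) / chi_act, S_b / chi_pri
            )
            if model == "BB" and prior.update_pi:
                k_in = int(included.sum())
                pi_zero = rng.beta(p - k_in + 1.0, k_in + 1.0)
                log_odds_prior = np.log(
                    max(1.0 - pi_zero, 1e-12) / max(pi_zero, 1e-12)
                )
            s2e = (S_e + e @ e) / rng.chisquare(df_e + n)
        else:  # BL
            babs = np.maximum(np.abs(b), 1e-10)
            inv_tau2 = _rinvgauss(rng, np.sqrt(lam2 * s2e) / babs, lam2)
            tau2 = 1.0 / inv_tau2
            lam2 = rng.gamma(
                lam_shape0 + p, 1.0 / (lam_rate0 + np.sum(tau2) / 2.0)
            )
            s2e = (S_e + e @ e + np.sum(b * b * inv_tau2)) / rng.chisquare(
                df_e + n + p
            )

        if not np.isfinite(s2e):
            raise SamplerError(f"non-finite sampler state at iteration {it}")

        if it >= burn_in:
            k = it - burn_in
            sum_mu += mu
            sum_b += b
            sum_b2 += b * b
            sum_s2e += s2e
            s2e_chain[k] = s2e
            if model in ("BA", "BB"):
                sum_s2b += s2b
            elif model == "BRR":
                sum_s2b += s2b_common
            if model == "BB":
                sum_incl += included

    post_b = sum_b / n_keep
    post_sd = np.sqrt(np.maximum(sum_b2 / n_keep - post_b**2, 0.0))
    post_mu = sum_mu / n_keep
    post_s2e = sum_s2e / n_keep

    # split-chain PSRF on sigma2_e (reported, not enforced)
    half = n_keep // 2
    c1, c2 = s2e_chain[:half], s2e_chain[half : 2 * half]
    w = 0.5 * (np.var(c1, ddof=1) + np.var(c2, ddof=1))
    bvar = half * np.var([c1.mean(), c2.mean()], ddof=1)
    rhat = float(np.sqrt((w * (half - 1) / half + bvar / half) / w)) if w > 0 else 1.0

    diagnostics: dict[str, Any] = {"rhat_sigma2_e": rhat}
    if model == "BB":
        diagnostics["inclusion_prob"] = sum_incl / n_keep
    if model == "BL":
        diagnostics["lambda2"] = float(lam2)

    sigma2_b_out: float | np.ndarray | None
    if model == "BRR":
        sigma2_b_out = float(np.asarray(sum_s2b) / n_keep)
    elif model in ("BA", "BB"):
        sigma2_b_out = sum_s2b / n_keep
    else:
        sigma2_b_out = None

    fit = LinearModelFit(
        algorithm=model,
        intercept=float(post_mu),
        marker_effects=post_b,
        sigma2_e=float(post_s2e),
        sigma2_b=sigma2_b_out,
        marker_ids=_marker_ids(G_train),
        effect_sd=post_sd,
        iterations=iterations,
        burn_in=burn_in,
        diagnostics=diagnostics,
    )
    fit.fitted_values = predict_linear(fit, G_train)
    return fit


def predict_linear(fit: LinearModelFit, G_new) -> np.ndarray:
    """Predict trait values: ``yhat = intercept + X_new @ marker_effects``."""
    X = np.asarray(
        G_new.X() if isinstance(G_new, GenotypeMatrix) else G_new, dtype=float
    )
    if X.ndim != 2 or X.shape[1] != len(fit.marker_effects):
        raise AlignmentError(
            f"marker mismatch: fit has {len(fit.marker_effects)} markers, "
            f"input has {X.shape[1] if X.ndim == 2 else 'non-2D'}"
        )
    if fit.marker_ids is not None and isinstance(G_new, GenotypeMatrix):
        if list(G_new.marker_ids) != list(fit.marker_ids):
            raise AlignmentError("marker ids/order differ from the training set")
    return fit.intercept + X @ fit.marker_effects
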