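"""PLS1 regression of a colour descriptor on biochemical predictors.

The model links one colour response (a*, b* or hue) to the seven
genotype-level biochemical factors: log anthocyanins, flavanols, flavonols,
hydroxycinnamic acids, dihydrochalcones, pH and water content.  NIPALS
extracts orthogonal latent components from the z-scored design; a new
component is retained only while it explains more than 1% of the response
dispersion.  Predictor relevance is scored by VIP (variable importance in
projection), normalised so that Σ VIP² equals the number of predictors;
predictors below the customary 0.8 cut-off are considered negligible.
Validation is a seeded 20% hold-out split scored by RMSE in original units.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlsModel",
    "ValidationReport",
    "fit_pls1",
    "vip_scores",
    "validate",
    "prepare_design",
    "PREDICTORS",
    "VIP_CUTOFF",
]

log = logging.getLogger(__name__)

VIP_CUTOFF = 0.8

#: Predictor columns of the biochemical design, in fixed order.
PREDICTORS = (
    "log_anthocyanins",
    "flavanols",
    "flavonols",
    "hydroxycinnamic_acids",
    "dihydrochalcones",
    "pH",
    "water_content",
)


@dataclass
class PlsModel:
    """Fitted PLS1 state (all arrays live in z-scored space)."""

    n_components: int
    weights: np.ndarray        # p × h
    x_loadings: np.ndarray     # p × h
    x_scores: np.ndarray       # n × h
    y_loadings: np.ndarray     # h
    r2y_per_component: np.ndarray
    r2y_cum: float
    coefficients: np.ndarray   # p, scaled space
    vip: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    predictor_names: tuple = ()
    threshold: float = 0.01

    @property
    def important(self) -> np.ndarray:
        """Boolean flags for predictors at or above the VIP cut-off."""
        return self.vip >= VIP_CUTOFF

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        """Predict the response in original (unscaled) units."""
        Xa = np.asarray(X, float)
        Z = (Xa - self.x_mean) / self.x_sd
        return self.y_mean + self.y_sd * (Z @ self.coefficients)


def _zscore(v: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m = v.mean(axis=0)
    s = v.std(axis=0, ddof=1)
    return (v - m) / s, m, s


def fit_pls1(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    *,
    threshold: float = 0.01,
    max_components: int | None = None,
) -> PlsModel:
    """Fit a single-response NIPALS PLS with the 1% component rule.

    Per component: w = Xᵀy/‖Xᵀy‖, t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt, then X
    and y are deflated.  Components are added while the incremental share of
    Y dispersion exceeds ``threshold``; at least one is always kept.
    """
    names = tuple(X.columns) if isinstance(X, pd.DataFrame) else ()
    Xa = np.asarray(X, float)
    ya = np.asarray(y, float).ravel()
    n, p = Xa.shape
    if ya.shape[0] != n:
        raise ValueError("X and y disagree on the number of observations")
    if np.isnan(Xa).any() or np.isnan(ya).any():
        raise ValueError("missing cells are not allowed")
    sd = Xa.std(axis=0, ddof=1)
    tol = 1e-10 * np.maximum(1.0, np.abs(Xa).max(axis=0))
    dead = [names[j] if names else str(j) for j in np.flatnonzero(sd <= tol)]
    if dead:
        raise ValueError(f"zero-variance predictor(s): {dead}")
    if ya.std(ddof=1) <= 1e-10 * max(1.0, float(np.abs(ya).max())):
        raise ValueError("constant response")
    if n <= p:
        log.warning("n=%d <= p=%d: PLS fit is poorly determined", n, p)
    Z, x_mean, x_sd = _zscore(Xa)
    u = (ya - ya.mean()) / ya.std(ddof=1)
    y_mean, y_sd = ya.mean(), ya.std(ddof=1)
    ss_y = float(u @ u)
    hmax = min(p, n - 1) if max_components is None else min(max_components, p, n - 1)

    W, P, T, Q, r2 = [], [], [], [], []
    Zd, ud = Z.copy(), u.copy()
    for _ in range(hmax):
        cov = Zd.T @ ud
        nc = np.linalg.norm(cov)
        if nc < 1e-12:
            break
        w = cov / nc
        t = Zd @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        pl = Zd.T @ t / tt
        q = float(ud @ t) / tt
        r2_h = q**2 * tt / ss_y
        if r2_h <= threshold and len(W) >= 1:
            break
        W.append(w)
        P.append(pl)
        T.append(t)
        Q.append(q)
        r2.append(r2_h)
        Zd = Zd - np.outer(t, pl)
        ud = ud - q * t
        if r2_h <= threshold:
            break
    Wm = np.column_stack(W)
    Pm = np.column_stack(P)
    Tm = np.column_stack(T)
    Qv = np.array(Q)
    coef = Wm @ np.linalg.solve(Pm.T @ Wm, Qv)
    model = PlsModel(
        n_components=len(W),
        weights=Wm,
        x_loadings=Pm,
        x_scores=Tm,
        y_loadings=Qv,
        r2y_per_component=np.array(r2),
        r2y_cum=float(np.sum(r2)),
        coefficients=coef,
        vip=np.empty(p),
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=float(y_mean),
        y_sd=float(y_sd),
        predictor_names=names,
        threshold=threshold,
    )
    model.vip = vip_scores(model)
    return model


def vip_scores(model: PlsModel) -> np.ndarray:
    """VIP_j = √( p · Σ_h SSY_h (w_jh/‖w_h‖)² / Σ_h SSY_h ).

    SSY_h is the response variance explained by component h, so VIP weighs
    each predictor's share of the projection by how much that component
    actually explains; Σ VIP² = p by construction.
    """
    if getattr(model, "weights", None) is None or model.weights.size == 0:
        raise ValueError("model is not fitted")
    W = model.weights
    p = W.shape[0]
    ssy = model.r2y_per_component  # proportional to explained SSY
    wnorm2 = (W**2) / (W**2).sum(axis=0)
    return np.sqrt(p * (wnorm2 @ ssy) / ssy.sum())


@dataclass
class ValidationReport:
    rmse_test: float
    r2_train: float
    test_fraction: float
    seed: int
    n_train: int
    n_test: int
    n_components: int


def validate(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    *,
    test_fraction: float = 0.2,
    seed: int = 0,
    threshold: float = 0.01,
    max_components: int | None = None,
) -> ValidationReport:
    """Hold-out validation: refit on a seeded 80/20 split, RMSE on the rest.

    The split seed is an explicit parameter — hold-out RMSE is reproducible
    only for a given seed and is otherwise a draw from the split
    distribution.
    """
    Xa = np.asarray(X, float)
    ya = np.asarray(y, float).ravel()
    n = len(ya)
    if n < 10:
        raise ValueError("need at least 10 observations to validate")
    n_test = int(round(n * test_fraction))
    if n_test < 1 or n_test >= n:
        raise ValueError(f"degenerate split: n_test={n_test} of n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    model = fit_pls1(
        Xa[train_idx], ya[train_idx], threshold=threshold, max_components=max_components
    )
    pred = model.predict(Xa[test_idx])
    rmse = float(np.sqrt(np.mean((pred - ya[test_idx]) ** 2)))
    return ValidationReport(
        rmse_test=rmse,
        r2_train=model.r2y_cum,
        test_fraction=test_fraction,
        seed=seed,
        n_train=len(train_idx),
        n_test=n_test,
        n_components=model.n_components,
    )


def prepare_design(
    profiles: pd.DataFrame,
    descriptors: pd.DataFrame,
    *,
    response: str = "hue_deg",
    genotype_col: str = "genotype_id",
) -> tuple[pd.DataFrame, pd.Series]:
    """Join biochemistry to colour descriptors into a (X, y) modelling pair.

    Predictors are the seven biochemical factors with anthocyanins
    log-transformed (their relation to colour is saturating); the response
    is one descriptor column (``a_mean``, ``b_mean`` or ``hue_deg``).  Rows
    with missing values are dropped with a logged count.
    """
    prof = profiles.set_index(genotype_col) if genotype_col in profiles.columns else profiles
    desc = descriptors.set_index(genotype_col) if genotype_col in descriptors.columns else descriptors
    common = prof.index.intersection(desc.index)
    if len(common) == 0:
        raise ValueError("no genotypes shared between profiles and descriptors")
    prof = prof.loc[common]
    X = pd.DataFrame(index=common)
    X["log_anthocyanins"] = np.log(prof["anthocyanins"].astype(float))
    for col in ("flavanols", "flavonols", "hydroxycinnamic_acids",
                "dihydrochalcones", "pH", "water_content"):
        X[col] = prof[col].astype(float)
    y = desc.loc[common, response].astype(float)
    ok = ~(X.isna().any(axis=1) | y.isna())
    dropped = int((~ok).sum())
    if dropped:
        log.warning("dropping %d genotype(s) with missing values", dropped)
    return X.loc[ok], y.loc[ok]
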