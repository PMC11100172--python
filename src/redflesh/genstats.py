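"""Genetic and multivariate statistics for genotype panels.

* Broad-sense heritability by intra-class correlation: the trait model is
  ``y_jk = µ + B_j + ε_jk`` with genotype effects B_j ~ N(0, σ²_B) and
  residuals ε_jk ~ N(0, σ²_ε); h² = σ²_B / (σ²_B + σ²_ε).  Variance
  components come from the one-way ANOVA method of moments, with the
  Satterthwaite-adjusted mean group size n₀ for unbalanced designs and
  negative σ²_B truncated to zero.

* Correlation-matrix PCA with supplementary variables: active variables are
  z-scored (population SD), components are eigenvectors of their correlation
  matrix, and supplementary variables are projected afterwards as plain
  correlations with the component scores — they never influence the
  decomposition.  Squared cosines (cos²) measure how well a variable or
  observation is represented on each component.

* Pairwise Pearson correlation matrix with a two-sided significance mask at
  p < 0.05 (unadjusted, by design — matches the descriptive use).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HeritabilityModel",
    "heritability",
    "PcaResult",
    "pca",
    "CorrelationMatrix",
    "correlation_matrix",
]


@dataclass
class HeritabilityModel:
    trait: str
    sigma2_B: float
    sigma2_eps: float
    h2: float
    n_groups: int
    replicates_per_group: float
    ms_between: float
    ms_within: float


def heritability(
    values: pd.DataFrame,
    *,
    group_col: str = "genotype_id",
    value_col: str = "value",
    trait: str = "",
) -> HeritabilityModel:
    """Intra-class-correlation heritability of one trait.

    ``values`` holds one row per observation (genotype × replicate, e.g. the
    genotype means of two harvest years).  Requires ≥ 2 genotypes and
    replication in at least one of them.
    """
    df = values[[group_col, value_col]].dropna()
    groups = [g[value_col].to_numpy(float) for _, g in df.groupby(group_col)]
    a = len(groups)
    if a < 2:
        raise ValueError("need at least 2 genotypes")
    sizes = np.array([len(g) for g in groups], float)
    N = sizes.sum()
    if (sizes > 1).sum() == 0 or N <= a:
        raise ValueError("no replication: variance components inestimable")
    grand = df[value_col].mean()
    ssb = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(sizes, groups)))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    msb = ssb / (a - 1)
    msw = ssw / (N - a)
    n0 = (N - (sizes**2).sum() / N) / (a - 1)  # Satterthwaite mean group size
    sigma2_eps = msw
    sigma2_B = max((msb - msw) / n0, 0.0)
    denom = sigma2_B + sigma2_eps
    h2 = sigma2_B / denom if denom > 0 else 0.0
    return HeritabilityModel(
        trait=trait,
        sigma2_B=sigma2_B,
        sigma2_eps=sigma2_eps,
        h2=min(max(h2, 0.0), 1.0),
        n_groups=a,
        replicates_per_group=float(n0),
        ms_between=msb,
        ms_within=msw,
    )


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    scores: pd.DataFrame
    loadings: pd.DataFrame
    cos2_var: pd.DataFrame
    cos2_obs: pd.DataFrame
    sup_correlations: pd.DataFrame | None = None
    mean_: pd.Series | None = None
    sd_: pd.Series | None = None


def pca(
    active: pd.DataFrame,
    supplementary: pd.DataFrame | None = None,
    *,
    n_components: int | None = None,
) -> PcaResult:
    """Correlation-matrix PCA with optional supplementary variables.

    Active variables are centred and reduced by their population SD, so the
    decomposition acts on the correlation matrix; loadings are the
    variable–component correlations (eigenvector × √eigenvalue) and cos² is
    their square.  Supplementary columns are correlated with the scores only.
    """
    X = active.to_numpy(float)
    n, p = X.shape
    if p < 2 or n < 3:
        raise ValueError("PCA needs >= 2 active variables and >= 3 observations")
    if np.isnan(X).any():
        raise ValueError("missing cells in active table")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD, FactoMineR-style reduction
    dead = [c for c, s in zip(active.columns, sd) if s == 0]
    if dead:
        raise ValueError(f"zero-variance active variable(s): {dead}")
    Z = (X - mean) / sd
    corr = Z.T @ Z / n
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign convention: make each component's largest-|loading| variable positive
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(p)])
    flip[flip == 0] = 1.0
    evecs = evecs * flip
    k = p if n_components is None else min(n_components, p)
    comp = [f"PC{i+1}" for i in range(k)]
    scores = Z @ evecs[:, :k]
    loadings = evecs[:, :k] * np.sqrt(evals[:k])
    pct = 100.0 * evals / evals.sum()
    cos2_var = loadings**2
    row_ss = (Z**2).sum(axis=1, keepdims=True)
    cos2_obs = np.where(row_ss > 0, scores**2 / row_ss, 0.0)
    sup = None
    if supplementary is not None:
        S = supplementary.to_numpy(float)
        sup = pd.DataFrame(
            _columnwise_corr(S, scores),
            index=supplementary.columns,
            columns=comp,
        )
    return PcaResult(
        eigenvalues=evals,
        pct_variance=pct,
        scores=pd.DataFrame(scores, index=active.index, columns=comp),
        loadings=pd.DataFrame(loadings, index=active.columns, columns=comp),
        cos2_var=pd.DataFrame(cos2_var, index=active.columns, columns=comp),
        cos2_obs=pd.DataFrame(cos2_obs, index=active.index, columns=comp),
        sup_correlations=sup,
        mean_=pd.Series(mean, index=active.columns),
        sd_=pd.Series(sd, index=active.columns),
    )


def _columnwise_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """corr(A[:, i], B[:, j]) for all pairs; NaN-pairs handled pairwise."""
    out = np.empty((A.shape[1], B.shape[1]))
    for i in range(A.shape[1]):
        ai = A[:, i]
        ok = ~np.isnan(ai)
        for j in range(B.shape[1]):
            bj = B[ok, j]
            av = ai[ok]
            sa, sb = av.std(), bj.std()
            if sa == 0 or sb == 0:
                out[i, j] = np.nan
            else:
                out[i, j] = ((av - av.mean()) * (bj - bj.mean())).mean() / (sa * sb)
    return out


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    mask: pd.DataFrame = field(default=None)
    alpha: float = 0.05


def correlation_matrix(table: pd.DataFrame, *, alpha: float = 0.05) -> CorrelationMatrix:
    """Pairwise Pearson r with two-sided p-values and a p < alpha mask.

    p comes from the t statistic r·√((n−2)/(1−r²)) on n−2 df.  Constant
    columns yield NaN correlations (flagged, never silently zeroed).
    """
    cols = list(table.columns)
    m = len(cols)
    r = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    X = table.to_numpy(float)
    for i in range(m):
        for j in range(i, m):
            xi, xj = X[:, i], X[:, j]
            ok = ~(np.isnan(xi) | np.isnan(xj))
            n = ok.sum()
            if n < 3 or xi[ok].std() == 0 or xj[ok].std() == 0:
                continue
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
                continue
            rij = np.corrcoef(xi[ok], xj[ok])[0, 1]
            rij = float(np.clip(rij, -1.0, 1.0))
            if abs(rij) == 1.0:
                pij = 0.0
            else:
                t = rij * np.sqrt((n - 2) / (1.0 - rij**2))
                pij = 2.0 * stats.t.sf(abs(t), df=n - 2)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    return CorrelationMatrix(r=rdf, p=pdf, mask=pdf < alpha, alpha=alpha)
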