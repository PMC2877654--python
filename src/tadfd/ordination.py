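"""Habitat ordination: Box-Cox screening, correlation PCA, loading tests.

The environmental stage reduces the 14 habitat variables recorded per
stream section to a few orthogonal gradients and asks which of them
predict species richness (SR).  Steps:

1. Variables with outlier-prone (heavily skewed) distributions are
   Box-Cox power-transformed; the transformed set is reported.
2. PCA on the correlation matrix (so unequal variances do not dominate).
3. Loadings are tested against zero with the bootstrapped-eigenvector
   method: sites are resampled with replacement, the PCA recomputed,
   axes re-aligned to the original solution by loading-vector
   congruence, and a loading is significant when its percentile
   interval excludes zero.
4. The number of meaningful components defaults to the broken-stick
   rule, with a manual override for scree-plot judgement calls.
5. SR is regressed on the retained component scores (no interactions)
   with backward elimination to a minimal adequate model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .tables import HabitatTable

__all__ = [
    "BoxCoxResult",
    "PCAResult",
    "SRRegression",
    "boxcox_transform",
    "transform_habitat",
    "run_pca",
    "broken_stick",
    "select_n_components",
    "bootstrap_eigenvector_test",
    "regress_sr_on_pcs",
    "ordinate",
]


# ----------------------------------------------------------------------
# Box-Cox
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class BoxCoxResult:
    transformed: np.ndarray
    lam: float
    offset: float


def boxcox_transform(values, grid_min: float = -2.0, grid_max: float = 2.0,
                     grid_step: float = 0.1) -> BoxCoxResult:
    """Box-Cox power transform with grid profile-likelihood selection.

    ``y = (x**lam - 1)/lam`` (log for lam = 0); lambda maximises the
    profile log-likelihood over the grid.  Zeros are handled by adding
    an offset of half the smallest positive value, which is recorded in
    the result.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("need a 1-D sample of at least 3 values")
    if np.ptp(x) == 0:
        raise ValueError("constant input cannot be Box-Cox transformed")
    if np.any(x < 0):
        raise ValueError("Box-Cox requires non-negative input")
    offset = 0.0
    if np.any(x == 0):
        offset = 0.5 * x[x > 0].min()
    xs = x + offset
    grid = np.arange(grid_min, grid_max + grid_step / 2, grid_step)
    grid[np.abs(grid) < 1e-12] = 0.0
    llf = np.array([stats.boxcox_llf(l, xs) for l in grid])
    lam = float(grid[int(np.argmax(llf))])
    transformed = stats.boxcox(xs, lmbda=lam)
    return BoxCoxResult(transformed=transformed, lam=lam, offset=offset)


def transform_habitat(habitat: HabitatTable, skew_threshold: float = 1.0):
    """Box-Cox transform the outlier-prone habitat variables.

    A variable qualifies when its absolute sample skewness exceeds
    ``skew_threshold`` (the operational reading of "contains outliers").
    Returns the transformed data frame and a record of what was done.
    """
    df = habitat.df.copy()
    applied = {}
    for col in df.columns:
        x = df[col].to_numpy()
        if abs(stats.skew(x)) > skew_threshold and np.ptp(x) > 0 and np.all(x >= 0):
            res = boxcox_transform(x)
            df[col] = res.transformed
            applied[col] = {"lambda": res.lam, "offset": res.offset}
    return df, applied


# ----------------------------------------------------------------------
# PCA on the correlation matrix
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class PCAResult:
    """Correlation-matrix PCA with optional bootstrap loading flags."""

    eigenvalues: np.ndarray
    proportions: np.ndarray
    loadings: pd.DataFrame          # variables x components (eigenvectors)
    scores: pd.DataFrame            # sites x components
    n_retained: int | None = None
    significant: pd.DataFrame | None = None
    boot_low: pd.DataFrame | None = None
    boot_high: pd.DataFrame | None = None
    n_redrawn: int = 0


def _pca_core(X: np.ndarray):
    """Eigendecomposition of the correlation matrix; loadings sign-fixed
    so each component's largest-magnitude loading is positive."""
    sd = X.std(axis=0, ddof=1)
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(X, rowvar=False)
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    for k in range(vecs.shape[1]):
        j = int(np.argmax(np.abs(vecs[:, k])))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    scores = Z @ vecs
    return vals, vecs, scores


def run_pca(data) -> PCAResult:
    """PCA of a site-by-variable table on the correlation matrix.

    Each variable is centred and scaled to unit variance, so the
    eigenvalues sum to the number of variables and the proportion of
    variance per component is eigenvalue / n_variables.
    """
    df = data.df if isinstance(data, HabitatTable) else pd.DataFrame(data)
    X = df.to_numpy(dtype=float)
    constant = df.columns[X.std(axis=0) == 0].tolist()
    if constant:
        raise ValueError(f"constant habitat variable(s): {constant}")
    vals, vecs, scores = _pca_core(X)
    comps = [f"PC{k + 1}" for k in range(len(vals))]
    return PCAResult(
        eigenvalues=vals,
        proportions=vals / vals.sum(),
        loadings=pd.DataFrame(vecs, index=df.columns, columns=comps),
        scores=pd.DataFrame(scores, index=df.index, columns=comps),
    )


def broken_stick(p: int) -> np.ndarray:
    """Broken-stick expected eigenvalue proportions: b_k = (1/p) sum_{j>=k} 1/j."""
    return np.array([sum(1.0 / j for j in range(k, p + 1)) / p for k in range(1, p + 1)])


def select_n_components(eigenvalues, override: int | None = None) -> int:
    """Retain the leading components that beat the broken-stick model.

    Counts components, from the first, whose variance proportion
    strictly exceeds the broken-stick expectation; ``override`` forces a
    manual (scree-plot style) choice instead.
    """
    vals = np.asarray(eigenvalues, dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 eigenvalues")
    if override is not None:
        if not 1 <= override <= len(vals):
            raise ValueError("override outside component range")
        return int(override)
    props = vals / vals.sum()
    expect = broken_stick(len(vals))
    n = 0
    for prop, exp in zip(props, expect):
        if prop > exp:
            n += 1
        else:
            break
    return n


def bootstrap_eigenvector_test(data, n_boot: int = 999, alpha: float = 0.05,
                               seed=None, n_components: int | None = None,
                               max_redraws: int = 1000) -> PCAResult:
    """Bootstrapped-eigenvector significance test for PCA loadings.

    Sites are resampled with replacement ``n_boot`` times and the PCA
    recomputed.  Each bootstrap solution's axes are matched to the
    original axes greedily by maximal absolute loading-vector inner
    product, with the sign flipped to positive congruence; a loading is
    flagged significant when its two-sided (1 - alpha) percentile
    interval over the aligned bootstrap loadings excludes zero.
    Resamples in which a variable degenerates to a constant are redrawn
    and counted.
    """
    if n_boot < 199:
        raise ValueError("n_boot must be at least 199 for percentile intervals")
    df = data.df if isinstance(data, HabitatTable) else pd.DataFrame(data)
    X = df.to_numpy(dtype=float)
    n, p = X.shape
    base = run_pca(df)
    K = p if n_components is None else int(n_components)
    V = base.loadings.to_numpy()[:, :K]

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, p, K))
    n_redrawn = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        Xb = X[idx]
        if np.any(Xb.std(axis=0) == 0):
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        _, W, _ = _pca_core(Xb)
        # greedy axis alignment by absolute congruence with sign flip
        remaining = list(range(p))
        aligned = np.empty((p, K))
        for k in range(K):
            dots = V[:, k] @ W[:, remaining]
            j = int(np.argmax(np.abs(dots)))
            sign = 1.0 if dots[j] >= 0 else -1.0
            aligned[:, k] = sign * W[:, remaining[j]]
            remaining.pop(j)
        boot[b] = aligned
        b += 1

    lo = np.percentile(boot, 100 * alpha / 2, axis=0)
    hi = np.percentile(boot, 100 * (1 - alpha / 2), axis=0)
    sig = (lo > 0) | (hi < 0)
    comps = list(base.loadings.columns[:K])
    return PCAResult(
        eigenvalues=base.eigenvalues,
        proportions=base.proportions,
        loadings=base.loadings,
        scores=base.scores,
        significant=pd.DataFrame(sig, index=df.columns, columns=comps),
        boot_low=pd.DataFrame(lo, index=df.columns, columns=comps),
        boot_high=pd.DataFrame(hi, index=df.columns, columns=comps),
        n_redrawn=n_redrawn,
    )


# ----------------------------------------------------------------------
# SR on principal components
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SRRegression:
    """Minimal adequate OLS model of SR on retained component scores."""

    coefficients: dict
    standard_errors: dict
    t_values: dict
    p_values: dict
    f_statistic: float
    df_num: int
    df_den: int
    r_squared: float
    eliminated: tuple  # ((component, p_at_removal), ...) in drop order
    retained: tuple


def regress_sr_on_pcs(scores: pd.DataFrame, sr, threshold: float = 0.05) -> SRRegression:
    """Backward-eliminate components until all remaining have p < threshold.

    Ordinary least squares of SR on the given component scores, no
    interactions.  The component with the worst p-value at or above the
    threshold is dropped, one at a time; the elimination trace is
    reported.  If every component is eliminated the intercept-only
    model is returned.
    """
    scores = pd.DataFrame(scores)
    if scores.shape[1] < 1:
        raise ValueError("need at least one retained component")
    y = np.asarray(sr, dtype=float)
    if len(y) != len(scores):
        raise ValueError("SR length does not match scores")
    current = list(scores.columns)
    trace = []
    while True:
        X = sm.add_constant(scores[current]) if current else \
            pd.DataFrame({"const": np.ones(len(y))}, index=scores.index)
        fit = sm.OLS(y, X).fit()
        if not current:
            break
        pvals = fit.pvalues.drop("const")
        worst = pvals.idxmax()
        if pvals[worst] >= threshold:
            trace.append((str(worst), float(pvals[worst])))
            current.remove(worst)
        else:
            break
    return SRRegression(
        coefficients={str(k): float(v) for k, v in fit.params.items()},
        standard_errors={str(k): float(v) for k, v in fit.bse.items()},
        t_values={str(k): float(v) for k, v in fit.tvalues.items()},
        p_values={str(k): float(v) for k, v in fit.pvalues.items()},
        f_statistic=float(fit.fvalue) if current else float("nan"),
        df_num=int(fit.df_model),
        df_den=int(fit.df_resid),
        r_squared=float(fit.rsquared),
        eliminated=tuple(trace),
        retained=tuple(str(c) for c in current),
    )


def ordinate(habitat: HabitatTable, sr, n_boot: int = 999, alpha: float = 0.05,
             seed=None, retain_override: int | None = None,
             threshold: float = 0.05, skew_threshold: float = 1.0) -> dict:
    """Full environmental stage: transform, PCA, loading test, SR model."""
    transformed, applied = transform_habitat(habitat, skew_threshold=skew_threshold)
    pca = bootstrap_eigenvector_test(transformed, n_boot=n_boot, alpha=alpha, seed=seed)
    n_retained = select_n_components(pca.eigenvalues, override=retain_override)
    n_model = max(n_retained, 1)
    reg = regress_sr_on_pcs(pca.scores.iloc[:, :n_model], sr, threshold=threshold)
    return {
        "transformed_variables": applied,
        "pca": pca,
        "n_retained": n_retained,
        "sr_regression": reg,
    }
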