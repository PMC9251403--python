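"""Site x season occurrence aggregation and binomial GLMs with diagnostics.

Occurrence of a diet taxon (here typically dog, and the fox's main prey,
field vole) is aggregated to site x season cells and modelled as an
aggregated binomial (k successes of n samples) with a logit link, with
either sampling season as a categorical covariate or vole frequency of
occurrence as a continuous one.  Model adequacy is checked with
simulation-based randomized-quantile residuals (uniformity, dispersion,
outliers) and a Moran's I test for spatial autocorrelation of residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

SEASON_ORDER = ("winter2018", "spring2018", "winter2019", "spring2019")

Z95 = 1.959963984540054  # two-sided 95% normal quantile


def _expit(eta: np.ndarray) -> np.ndarray:
    return stats.logistic.cdf(eta)


def aggregate_site_season(
    occurrences: pd.DataFrame,
    assignments: pd.DataFrame,
    metadata: pd.DataFrame,
    predator: str = "Vulpes vulpes",
    dog_taxon: str = "Canis lupus familiaris",
    vole_taxon: str = "Microtus agrestis",
) -> pd.DataFrame:
    """One row per site x season cell with dog/vole occurrence counts.

    Columns: site_id, season, n, n_dog_positive, n_vole_positive, vole_fo
    (percent), x, y (site centroid of the included samples).  Cells without
    predator samples are omitted, not zero-filled.
    """
    meta = metadata.set_index("sample_id")
    pred_samples = assignments.index[assignments["host"] == predator]
    unknown = [s for s in pred_samples if s not in meta.index]
    if unknown:
        raise ValueError(f"samples without metadata: {unknown[:10]}")
    det = occurrences[occurrences["detected"]]
    dog_pos = set(det.loc[det["taxon"] == dog_taxon, "sample_id"])
    vole_pos = set(det.loc[det["taxon"] == vole_taxon, "sample_id"])
    rows = []
    sub = meta.loc[list(pred_samples)]
    for (site, season), grp in sub.groupby(["site_id", "season"], sort=False):
        n = len(grp)
        k_dog = sum(s in dog_pos for s in grp.index)
        k_vole = sum(s in vole_pos for s in grp.index)
        rows.append({
            "site_id": site, "season": season, "n": n,
            "n_dog_positive": k_dog, "n_vole_positive": k_vole,
            "vole_fo": 100.0 * k_vole / n,
            "x": float(grp["x_coord"].mean()), "y": float(grp["y_coord"].mean()),
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        order = {s: i for i, s in enumerate(SEASON_ORDER)}
        out = out.sort_values(
            ["season", "site_id"],
            key=lambda c: c.map(order) if c.name == "season" else c,
        ).reset_index(drop=True)
    return out


@dataclass
class GLMFit:
    """A fitted aggregated-binomial logistic model."""

    params: pd.Series            # log-odds scale coefficients
    cov: pd.DataFrame            # coefficient covariance (observed information)
    deviance: float
    converged: bool
    separation_flag: bool
    design_kind: str             # "intercept" | "season" | "vole_fo"
    season_levels: tuple[str, ...] | None
    fitted: pd.DataFrame         # per observation: prob, ci_low, ci_high
    k: np.ndarray
    n: np.ndarray
    X: np.ndarray

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return X @ self.params.to_numpy()


def _design(
    data: pd.DataFrame, design: str
) -> tuple[np.ndarray, list[str], tuple[str, ...] | None]:
    if design == "intercept":
        return np.ones((len(data), 1)), ["intercept"], None
    if design == "season":
        levels = tuple(s for s in SEASON_ORDER if s in set(data["season"]))
        levels = levels or tuple(dict.fromkeys(data["season"]))
        X = np.ones((len(data), len(levels)))
        names = ["intercept"]
        for j, lev in enumerate(levels[1:], start=1):
            X[:, j] = (data["season"] == lev).to_numpy(float)
            names.append(f"season[{lev}]")
        return X, names, levels
    if design == "vole_fo":
        # vole FO enters internally as a proportion for coefficient-scale stability
        X = np.column_stack([np.ones(len(data)), data["vole_fo"].to_numpy() / 100.0])
        return X, ["intercept", "vole_fo"], None
    raise ValueError(f"unknown design {design!r}")


def fit_binomial_glm(data: pd.DataFrame, design: str = "season",
                     response: str = "dog") -> GLMFit:
    """Fit k-of-n logistic regression by IRLS.

    ``data`` is the site x season aggregate; ``response`` selects the
    ``n_dog_positive`` or ``n_vole_positive`` column (or pass a DataFrame
    with explicit ``k`` and ``n`` columns and ``response='k'``).
    Convergence: relative deviance change < 1e-10 within 100 iterations.
    """
    kcol = {"dog": "n_dog_positive", "vole": "n_vole_positive", "k": "k"}[response]
    k = data[kcol].to_numpy(float)
    n = data["n"].to_numpy(float)
    if (n <= 0).any():
        raise ValueError("all cells must have at least one trial")
    if (k > n).any() or (k < 0).any():
        raise ValueError("successes must lie in [0, n]")
    X, names, season_levels = _design(data, design)
    model = sm.GLM(np.column_stack([k, n - k]), X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100, tol=1e-10)
    params = pd.Series(res.params, index=names)
    cov = pd.DataFrame(res.cov_params(), index=names, columns=names)
    se = np.sqrt(np.diag(cov))
    separation = bool(np.any(np.abs(params.to_numpy()) > 15) or np.any(se > 1e3))
    if separation:
        warnings.warn("possible complete separation: coefficients unreliable")
    eta = X @ res.params
    eta_se = np.sqrt(np.einsum("ij,jk,ik->i", X, cov.to_numpy(), X))
    prob = _expit(eta)
    lo = _expit(eta - Z95 * eta_se)
    hi = _expit(eta + Z95 * eta_se)
    fitted = pd.DataFrame({"prob": prob, "ci_low": lo, "ci_high": hi})
    return GLMFit(
        params=params, cov=cov, deviance=float(res.deviance),
        converged=bool(res.converged), separation_flag=separation,
        design_kind=design, season_levels=season_levels,
        fitted=fitted, k=k, n=n, X=X,
    )


def wald_pvalues(fit: GLMFit) -> pd.Series:
    se = np.sqrt(np.diag(fit.cov.to_numpy()))
    z = fit.params.to_numpy() / se
    return pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=fit.params.index)


def predict_with_ci(fit: GLMFit, newdata: pd.DataFrame) -> pd.DataFrame:
    """Response-scale predictions with logit-scale Wald 95% intervals."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    if fit.design_kind == "season":
        unknown = set(newdata["season"]) - set(fit.season_levels)
        if unknown:
            raise ValueError(f"unknown season levels: {sorted(unknown)}")
        X = np.ones((len(newdata), len(fit.season_levels)))
        for j, lev in enumerate(fit.season_levels[1:], start=1):
            X[:, j] = (newdata["season"] == lev).to_numpy(float)
    elif fit.design_kind == "vole_fo":
        X = np.column_stack(
            [np.ones(len(newdata)), newdata["vole_fo"].to_numpy() / 100.0])
    else:
        X = np.ones((len(newdata), 1))
    eta = X @ fit.params.to_numpy()
    eta_se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov.to_numpy(), X))
    return pd.DataFrame({
        "prob": _expit(eta),
        "ci_low": _expit(eta - Z95 * eta_se),
        "ci_high": _expit(eta + Z95 * eta_se),
    }, index=newdata.index)


@dataclass(frozen=True)
class ResidualDiagnostics:
    uniformity_p: float     # KS test of randomized-quantile residuals vs U(0,1)
    dispersion_ratio: float  # var(observed Pearson) / mean var(simulated Pearson)
    n_outliers: int          # observations outside the simulated envelope
    residuals: np.ndarray    # the randomized-quantile residuals


def residual_diagnostics(fit: GLMFit, observed: np.ndarray | None = None,
                         n_sim: int = 250,
                         seed: int | None = None) -> ResidualDiagnostics:
    """Simulation-based residual checks for an aggregated-binomial fit.

    Simulates ``n_sim`` datasets from the fitted model, computes per
    observation the randomized-quantile residual (rank of the observed count
    among simulated ones, uniform jitter over ties), and reports a KS
    uniformity p value, the Pearson-residual dispersion ratio, and the count
    of observations outside the simulated envelope.

    ``observed`` defaults to the counts the model was fitted to; pass new
    counts to diagnose other data under the same fitted model (note that
    residuals of the fitting data themselves are slightly conservative, as
    the fit has adapted to them).
    """
    if n_sim < 20:
        raise ValueError("n_sim must be >= 20")
    rng = np.random.default_rng(seed)
    p = fit.fitted["prob"].to_numpy()
    n = fit.n.astype(int)
    k = fit.k.astype(int) if observed is None else np.asarray(observed, int)
    if len(k) != len(n):
        raise ValueError("observed counts must match the fitted design length")
    sims = rng.binomial(n[None, :], p[None, :], size=(n_sim, len(n)))
    below = (sims < k[None, :]).sum(axis=0)
    equal = (sims == k[None, :]).sum(axis=0)
    u = (below + rng.uniform(size=len(n)) * (equal + 1)) / (n_sim + 1)
    ks = stats.kstest(u, "uniform")
    sd = np.sqrt(n * p * (1 - p))
    sd = np.where(sd == 0, 1.0, sd)
    pearson_obs = (k - n * p) / sd
    pearson_sim = (sims - n[None, :] * p[None, :]) / sd[None, :]
    dispersion = float(np.var(pearson_obs) / np.mean(np.var(pearson_sim, axis=1)))
    outliers = int(((k < sims.min(axis=0)) | (k > sims.max(axis=0))).sum())
    return ResidualDiagnostics(
        uniformity_p=float(ks.pvalue), dispersion_ratio=dispersion,
        n_outliers=outliers, residuals=u,
    )


@dataclass(frozen=True)
class MoranResult:
    moran_i: float
    expected: float  # -1/(m-1) for m locations
    p_value: float   # two-sided, normal approximation


def spatial_autocorrelation_test(
    residuals: np.ndarray, coordinates: np.ndarray
) -> MoranResult:
    """Moran's I with row-standardized inverse-distance weights.

    Duplicate coordinates are collapsed by averaging their residuals (a
    shared location contributes one value). Significance via the normal
    approximation under the normality assumption.
    """
    residuals = np.asarray(residuals, float)
    coordinates = np.asarray(coordinates, float)
    if not np.isfinite(coordinates).all():
        raise ValueError("coordinates must be finite")
    # collapse duplicate locations
    uniq, inv = np.unique(coordinates, axis=0, return_inverse=True)
    if len(uniq) < len(coordinates):
        collapsed = np.array([residuals[inv == i].mean() for i in range(len(uniq))])
        residuals, coordinates = collapsed, uniq
    m = len(residuals)
    if m < 3:
        raise ValueError("need at least 3 distinct locations")
    d = np.sqrt(((coordinates[:, None, :] - coordinates[None, :, :]) ** 2).sum(-1))
    if np.all(d[~np.eye(m, dtype=bool)] == 0):
        raise ValueError("all locations identical")
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    w /= w.sum(axis=1, keepdims=True)
    z = residuals - residuals.mean()
    s0 = w.sum()
    moran = (m / s0) * (z @ w @ z) / (z @ z)
    expected = -1.0 / (m - 1)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    var = ((m * m * s1 - m * s2 + 3 * s0 * s0)
           / (s0 * s0 * (m * m - 1))) - expected ** 2
    zscore = (moran - expected) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(zscore))
    return MoranResult(moran_i=float(moran), expected=float(expected), p_value=float(p))
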