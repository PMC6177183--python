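"""Mixed-effects comparison of sensing sites.

Each dynamic parameter (delay, time constant, time to 50% max, time to
50% decline) is analysed with a linear mixed model fitted by maximum
likelihood: sensor site, fluid regimen and (for intraperitoneal sensors)
element orientation as fixed effects, pig as a random intercept.
Pairwise site contrasts and the pooled IP-vs-SC contrast are tested with
t-tests whose degrees of freedom come from the Satterthwaite
approximation; the significance threshold is fixed at alpha = 0.01 to
account for multiplicity, with no further correction.

Estimation is delegated to statsmodels MixedLM. statsmodels provides no
Satterthwaite degrees of freedom, so they are computed here by the delta
method on the profile log-likelihood of the random-intercept model
(the same construction lmerTest uses), and cross-checked against
lmerTest in the test suite.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM

ALPHA = 0.01
RESPONSES = ("theta_s", "tau_s", "t50max_min", "t50decline_min")


@dataclass(frozen=True)
class LMMSpec:
    """Model specification for one dynamic parameter."""

    response: str = "theta_s"
    fixed: tuple[str, ...] = ("site", "fluid_regimen", "orientation")
    alpha: float = ALPHA
    site_reference: str = "IP_cranial_right"

    def __post_init__(self) -> None:
        if self.response not in RESPONSES:
            raise ValueError(f"unknown response {self.response!r}")


@dataclass
class LMMFit:
    """Fitted random-intercept model plus everything contrasts need."""

    spec: LMMSpec
    fe_params: pd.Series
    sigma2_e: float
    sigma2_b: float
    loglike: float
    singular: bool
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    groups: np.ndarray = field(repr=False)
    exog_names: list[str] = field(default_factory=list)

    def contrast_vector(self, name_a: str, name_b: str | None = None) -> np.ndarray:
        """c for the difference (level a - level b) of a dummy-coded factor;
        the reference level maps to the zero vector."""
        c = np.zeros(len(self.exog_names))
        for name, sign in ((name_a, 1.0), (name_b, -1.0)):
            if name is None:
                continue
            col = f"site[{name}]" if f"site[{name}]" in self.exog_names else name
            if col in self.exog_names:
                c[self.exog_names.index(col)] += sign
            elif name not in (self.spec.site_reference, "_ref"):
                raise ValueError(f"level {name!r} absent from the fitted model")
        return c


@dataclass
class ContrastResult:
    contrast: str
    estimate: float
    se: float
    df: float
    p_value: float
    significant: bool


def _design(table: pd.DataFrame, spec: LMMSpec,
            site_col: str = "site") -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design matrix with an intercept."""
    cols: list[np.ndarray] = [np.ones(len(table))]
    names = ["Intercept"]
    if "site" in spec.fixed:
        levels = [l for l in _ordered_levels(table[site_col])
                  if l != spec.site_reference]
        if spec.site_reference not in set(table[site_col]):
            levels = _ordered_levels(table[site_col])[1:]
        for lev in levels:
            cols.append((table[site_col] == lev).to_numpy(float))
            names.append(f"site[{lev}]")
    if "fluid_regimen" in spec.fixed and table["fluid_regimen"].nunique() > 1:
        cols.append((table["fluid_regimen"] == "low").to_numpy(float))
        names.append("fluid_regimen[low]")
    if ("orientation" in spec.fixed and "orientation" in table
            and set(table["orientation"]) - {"n/a"}
            and table["orientation"].nunique() > 1):
        cols.append((table["orientation"] == "toward_viscera").to_numpy(float))
        names.append("orientation[toward_viscera]")
    return np.column_stack(cols), names


def _ordered_levels(s: pd.Series) -> list[str]:
    seen: list[str] = []
    for v in s:
        if v not in seen:
            seen.append(v)
    return seen


def fit_lmm(table: pd.DataFrame, spec: LMMSpec | None = None,
            site_col: str = "site") -> LMMFit:
    """ML random-intercept fit of one dynamic parameter.

    ``table`` holds included records only, one row per recording x
    challenge, with columns for the response, site, covariates and
    pig_id. A boundary fit (pig variance ~ 0) is flagged, not fatal.
    """
    spec = spec or LMMSpec()
    if "included" in table:
        table = table[table["included"]]
    table = table.dropna(subset=[spec.response]).reset_index(drop=True)
    if table["pig_id"].nunique() < 2:
        raise ValueError("need at least 2 pigs")
    X, names = _design(table, spec, site_col)
    y = table[spec.response].to_numpy(float)
    groups = table["pig_id"].to_numpy()

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(y, X, groups=groups)
            res = model.fit(reml=False, method=["lbfgs", "powell"])
        sigma2_e = float(res.scale)
        sigma2_b = float(np.asarray(res.cov_re)[0, 0])
        fe = np.asarray(res.fe_params)
        llf = float(res.llf)
    except np.linalg.LinAlgError:
        # boundary fit (pig variance ~ 0) breaks the post-fit Hessian
        # inversion; maximize the closed-form profile likelihood instead
        sigma2_e, sigma2_b, fe, llf = _fit_profile_ml(X, y, groups)
    singular = sigma2_b < 1e-8 * max(sigma2_e, 1e-12)
    return LMMFit(
        spec=spec,
        fe_params=pd.Series(fe, index=names),
        sigma2_e=sigma2_e,
        sigma2_b=max(sigma2_b, 0.0),
        loglike=llf,
        singular=singular,
        X=X, y=y, groups=groups, exog_names=names,
    )


def _fit_profile_ml(X: np.ndarray, y: np.ndarray, groups: np.ndarray
                    ) -> tuple[float, float, np.ndarray, float]:
    """Direct ML on the profile likelihood of the random-intercept model.

    Parameterized as (log sigma2_e, sqrt sigma2_b) so the boundary
    sigma2_b = 0 is reachable.
    """
    from scipy.optimize import minimize

    gidx = _group_index(groups)
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    s2_tot = float(resid @ resid / max(len(y) - X.shape[1], 1))

    def nll(p):
        s2e = np.exp(p[0])
        s2b = p[1] ** 2
        return -profile_loglik((s2e, s2b), X, y, groups)

    best = None
    for frac in (0.5, 0.05):
        x0 = np.array([np.log(s2_tot * (1 - frac)), np.sqrt(s2_tot * frac)])
        r = minimize(nll, x0, method="Nelder-Mead",
                     options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if best is None or r.fun < best.fun:
            best = r
    s2e = float(np.exp(best.x[0]))
    s2b = float(best.x[1] ** 2)
    beta, _, _, _ = _gls((s2e, s2b), X, y, gidx)
    return s2e, s2b, beta, float(-best.fun)


# -- profile log-likelihood machinery (Satterthwaite df) --------------------

def _group_index(groups: np.ndarray) -> list[np.ndarray]:
    _, inv = np.unique(groups, return_inverse=True)
    return [np.flatnonzero(inv == k) for k in range(inv.max() + 1)]


def _gls(theta: tuple[float, float], X: np.ndarray, y: np.ndarray,
         gidx: list[np.ndarray]):
    """GLS quantities under Sigma_i = s2e I + s2b J (Woodbury)."""
    s2e, s2b = theta
    XtSX = np.zeros((X.shape[1], X.shape[1]))
    XtSy = np.zeros(X.shape[1])
    logdet = 0.0
    quad_parts = []
    for idx in gidx:
        Xi, yi = X[idx], y[idx]
        ni = len(idx)
        d = s2e + ni * s2b
        # Sigma^-1 z = z/s2e - (s2b/(s2e*d)) * sum(z) * 1
        xs = Xi.sum(axis=0)
        ys_ = yi.sum()
        XtSX += Xi.T @ Xi / s2e - np.outer(xs, xs) * (s2b / (s2e * d))
        XtSy += Xi.T @ yi / s2e - xs * ys_ * (s2b / (s2e * d))
        logdet += (ni - 1) * np.log(s2e) + np.log(d)
        quad_parts.append((Xi, yi, ni, d))
    beta = np.linalg.solve(XtSX, XtSy)
    quad = 0.0
    for Xi, yi, ni, d in quad_parts:
        r = yi - Xi @ beta
        rs = r.sum()
        quad += r @ r / s2e - (s2b / (s2e * d)) * rs * rs
    return beta, XtSX, logdet, quad


def profile_loglik(theta: tuple[float, float], X: np.ndarray, y: np.ndarray,
                   groups: np.ndarray) -> float:
    """ML log-likelihood with beta profiled out at fixed variance components."""
    gidx = _group_index(groups)
    _, _, logdet, quad = _gls(theta, X, y, gidx)
    n = len(y)
    return -0.5 * (n * np.log(2 * np.pi) + logdet + quad)


def _contrast_var(theta, X, y, gidx, c) -> float:
    _, XtSX, _, _ = _gls(theta, X, y, gidx)
    return float(c @ np.linalg.solve(XtSX, c))


def satterthwaite_contrast(fit: LMMFit, c: np.ndarray, label: str,
                           alpha: float | None = None) -> ContrastResult:
    """t-test of c'beta with Satterthwaite effective degrees of freedom.

    df = 2 v^2 / (g' A g) with v = Var(c'beta_hat), g its gradient in the
    variance components and A the inverse observed information of the
    profile log-likelihood. At a boundary (singular) fit the classical
    residual df is used instead.
    """
    alpha = fit.spec.alpha if alpha is None else alpha
    gidx = _group_index(fit.groups)
    theta = np.array([fit.sigma2_e, max(fit.sigma2_b, 0.0)])
    est = float(c @ fit.fe_params.to_numpy())
    v = _contrast_var(theta, fit.X, fit.y, gidx, c)
    se = float(np.sqrt(v))
    n, p = fit.X.shape
    if fit.singular:
        df = float(n - p)
    else:
        h = np.maximum(1e-4 * theta, 1e-10)
        grad = np.zeros(2)
        H = np.zeros((2, 2))
        f0 = profile_loglik(tuple(theta), fit.X, fit.y, fit.groups)
        for i in range(2):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h[i]
            tm[i] -= h[i]
            grad[i] = (_contrast_var(tp, fit.X, fit.y, gidx, c)
                       - _contrast_var(tm, fit.X, fit.y, gidx, c)) / (2 * h[i])
            H[i, i] = (profile_loglik(tuple(tp), fit.X, fit.y, fit.groups)
                       - 2 * f0
                       + profile_loglik(tuple(tm), fit.X, fit.y, fit.groups)) / h[i] ** 2
        tpp = theta + h
        tmm = theta - h
        tpm = theta + np.array([h[0], -h[1]])
        tmp = theta + np.array([-h[0], h[1]])
        H[0, 1] = H[1, 0] = (
            profile_loglik(tuple(tpp), fit.X, fit.y, fit.groups)
            - profile_loglik(tuple(tpm), fit.X, fit.y, fit.groups)
            - profile_loglik(tuple(tmp), fit.X, fit.y, fit.groups)
            + profile_loglik(tuple(tmm), fit.X, fit.y, fit.groups)
        ) / (4 * h[0] * h[1])
        try:
            A = np.linalg.inv(-H)
            denom = float(grad @ A @ grad)
            df = 2 * v**2 / denom if denom > 0 else float(n - p)
        except np.linalg.LinAlgError:
            df = float(n - p)
        df = float(np.clip(df, 1.0, n - p))
    if se == 0:
        t, pval = 0.0, 1.0
    else:
        t = est / se
        pval = float(2 * sps.t.sf(abs(t), df))
    return ContrastResult(label, est, se, df, pval, bool(pval < alpha))


IP_SITE_LEVELS = ("IP_cranial_right", "IP_cranial_left",
                  "IP_caudal_right", "IP_caudal_left")


def pairwise_site_tests(table: pd.DataFrame, response: str = "theta_s",
                        alpha: float = ALPHA,
                        include_covariates: bool = True) -> list[ContrastResult]:
    """The six IP-quadrant pairwise contrasts plus pooled IP vs SC.

    Quadrant contrasts come from an IP-only model with 4-level site (and
    orientation/regimen covariates); the pooled contrast from a model on
    all records with a binary IP/SC location factor (and regimen).
    """
    fixed = ("site", "fluid_regimen", "orientation") if include_covariates \
        else ("site",)
    results: list[ContrastResult] = []

    ip = table[table["site"].str.startswith("IP_")].copy()
    spec_ip = LMMSpec(response=response, fixed=fixed, alpha=alpha)
    fit_ip = fit_lmm(ip, spec_ip)
    for i, a in enumerate(IP_SITE_LEVELS):
        for b in IP_SITE_LEVELS[i + 1:]:
            if a not in set(ip["site"]) or b not in set(ip["site"]):
                raise ValueError(f"contrast references absent level: {a} or {b}")
            c = fit_ip.contrast_vector(a, b)
            results.append(satterthwaite_contrast(fit_ip, c, f"{a} - {b}", alpha))

    full = table.copy()
    full["location"] = np.where(full["site"].str.startswith("IP_"), "IP", "SC")
    fixed_loc = ("site", "fluid_regimen") if include_covariates else ("site",)
    spec_loc = LMMSpec(response=response, fixed=fixed_loc, alpha=alpha,
                       site_reference="IP")
    fit_loc = fit_lmm(full, spec_loc, site_col="location")
    c = fit_loc.contrast_vector("SC")
    results.append(satterthwaite_contrast(fit_loc, -c, "IP - SC", alpha))
    return results


SUMMARY_COLUMNS = {
    "theta_s": "time delay (s)",
    "tau_min": "time constant (min)",
    "fit_pct": "model fit (%)",
    "t50max_min": "time to 50% max (min)",
    "t50decline_min": "time to 50% decline (min)",
}


def summarize_sites(table: pd.DataFrame) -> pd.DataFrame:
    """Per-site mean +/- SD rows plus pooled All IP / All SC rows.

    Column layout mirrors the study's summary table: delay, time
    constant, model fit percentage, time to 50% max and 50% decline.
    Groups with a single record get SD = NaN; empty groups emit explicit
    missing markers.
    """
    tab = table[table["included"]].copy() if "included" in table else table.copy()
    if "tau_s" in tab and "tau_min" not in tab:
        tab["tau_min"] = tab["tau_s"] / 60.0
    rows = []
    site_order = list(IP_SITE_LEVELS) + ["SC_left", "SC_right"]
    groups: list[tuple[str, pd.DataFrame]] = [
        (s, tab[tab["site"] == s]) for s in site_order
    ]
    groups.append(("All IP", tab[tab["site"].str.startswith("IP_")]))
    groups.append(("All SC", tab[tab["site"].str.startswith("SC_")]))
    for label, g in groups:
        row: dict[str, object] = {"site": label, "n": len(g)}
        for col in SUMMARY_COLUMNS:
            if col in g and g[col].notna().any():
                row[f"{col}_mean"] = float(g[col].mean())
                row[f"{col}_sd"] = float(g[col].std(ddof=1)) if g[col].notna().sum() > 1 else np.nan
            else:
                row[f"{col}_mean"] = np.nan
                row[f"{col}_sd"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
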