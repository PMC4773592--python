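"""Mixed-effects inference for RT, accuracy, CAF, and delta analyses.

Reaction times are analyzed with Gaussian linear mixed models (REML,
participant random intercept) via statsmodels.  Binary accuracy is analyzed
with a logistic random-intercept mixed model estimated by maximum
likelihood with a Laplace approximation to the marginal likelihood; the
implementation lives here because the scientific-Python stack has no
frequentist GLMM solver (statsmodels offers a Bayesian variant, which the
test suite uses as an independent cross-check).

Post hoc congruence-by-bin contrasts are z-tests on the fitted log-odds
scale with single-step max-|z| multiplicity adjustment computed from the
joint normal distribution of the contrast estimates (Tukey-style
``glht``-type adjustment); Holm–Bonferroni is available as a deterministic
fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.numdiff import approx_hess3

__all__ = ["ModelFit", "Contrast", "SeparationError",
           "fit_rt_lmm", "fit_acc_glmm", "fit_caf_glmm",
           "posthoc_congruence_by_bin", "fit_delta_lmm"]


class SeparationError(RuntimeError):
    """Accuracy data admit a perfect (degenerate) logistic fit."""


@dataclass
class ModelFit:
    formula: str
    fixed_effects: list[tuple[str, float, float]]   # (name, estimate, SE)
    random_intercept_sd: float
    test: tuple[str, float, float, float, float]    # (name, stat, df1, df2, p)
    n_obs: int
    singular: bool = False
    extra_tests: dict[str, tuple[float, float, float, float]] = field(
        default_factory=dict)  # name -> (stat, df1, df2, p)
    cov_fixed: np.ndarray | None = None
    fe_names: list[str] = field(default_factory=list)

    def fixed_effect(self, name_fragment: str) -> tuple[str, float, float]:
        for fe in self.fixed_effects:
            if name_fragment in fe[0]:
                return fe
        raise KeyError(name_fragment)

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "fixed_effects": [
                {"name": n, "estimate": e, "se": s}
                for n, e, s in self.fixed_effects
            ],
            "random_intercept_sd": self.random_intercept_sd,
            "test": {
                "name": self.test[0], "statistic": self.test[1],
                "df1": self.test[2], "df2": self.test[3], "p": self.test[4],
            },
            "extra_tests": {
                k: {"statistic": v[0], "df1": v[1], "df2": v[2], "p": v[3]}
                for k, v in self.extra_tests.items()
            },
            "n_obs": self.n_obs,
            "singular": self.singular,
        }


@dataclass
class Contrast:
    label: str
    estimate: float
    se: float
    z_value: float
    p_value: float
    p_adjusted: float

    def to_dict(self) -> dict:
        return {
            "label": self.label, "estimate": self.estimate, "se": self.se,
            "z": self.z_value, "p": self.p_value, "p_adj": self.p_adjusted,
        }


def _included_responded(results: pd.DataFrame) -> pd.DataFrame:
    df = results
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    if "response_side" in df.columns:
        df = df[df["response_side"] != "none"]
    return df


def _residual_f_test(est: float, se: float, n_obs: int, k_params: int,
                     name: str = "F") -> tuple[str, float, float, float, float]:
    """Wald F with 1 numerator df and residual-df denominator convention."""
    f = (est / se) ** 2
    df2 = max(n_obs - k_params, 1)
    p = float(stats.f.sf(f, 1, df2))
    return (name, float(f), 1.0, float(df2), p)


def fit_rt_lmm(results: pd.DataFrame, correct_only: bool = True) -> ModelFit:
    """Linear mixed model RT ~ congruence with participant random intercept.

    REML estimation; the congruence effect is reported in ms (incongruent
    minus congruent) with a Wald F test using the residual-df convention.
    By default only correct trials enter, matching the delta-plot
    convention for RT analyses.
    """
    df = _included_responded(results).copy()
    if correct_only and "correct" in df.columns:
        df = df[df["correct"].astype(bool)]
    if df["congruence"].nunique() < 2:
        raise ValueError("need both congruence conditions to estimate the effect")
    if df["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants for a random intercept")
    df["congruence"] = pd.Categorical(
        df["congruence"], categories=["congruent", "incongruent"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            "rt_ms ~ congruence", groups="participant_id", data=df)
        res = model.fit(reml=True)
    re_var = float(np.asarray(res.cov_re).ravel()[0])
    singular = re_var < 1e-8
    name = "congruence[T.incongruent]"
    est = float(res.params[name])
    se = float(res.bse[name])
    fe = [(n, float(res.params[n]), float(res.bse[n])) for n in res.fe_params.index]
    k = len(fe)
    return ModelFit(
        formula="rt_ms ~ congruence + (1 | participant)",
        fixed_effects=fe,
        random_intercept_sd=float(np.sqrt(max(re_var, 0.0))),
        test=_residual_f_test(est, se, len(df), k + 1, "F(congruence)"),
        n_obs=len(df),
        singular=singular,
        cov_fixed=np.asarray(res.cov_params())[:k, :k],
        fe_names=list(res.fe_params.index),
    )


# ---------------------------------------------------------------------------
# logistic random-intercept mixed model (Laplace ML)

def _glmm_loglik(params: np.ndarray, X: np.ndarray, y: np.ndarray,
                 group_idx: np.ndarray, n_groups: int) -> float:
    """Laplace-approximate marginal log-likelihood.

    ``params`` is (beta..., log sigma_u).  The inner mode per group is
    found by a damped Newton iteration on the random intercept.
    """
    beta, log_s = params[:-1], params[-1]
    sigma2 = np.exp(2.0 * log_s)
    eta0 = X @ beta
    u = np.zeros(n_groups)
    for _ in range(50):
        eta = eta0 + u[group_idx]
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = np.bincount(group_idx, weights=y - p, minlength=n_groups)
        grad -= u / sigma2
        w = np.bincount(group_idx, weights=p * (1 - p), minlength=n_groups)
        hess = w + 1.0 / sigma2
        step = grad / hess
        u += np.clip(step, -5.0, 5.0)
        if np.max(np.abs(step)) < 1e-8:
            break
    eta = eta0 + u[group_idx]
    # log p(y | u) with stable log(1 + e^eta)
    ll_cond = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    ll_prior = float(-0.5 * np.sum(u**2) / sigma2
                     - 0.5 * n_groups * np.log(2 * np.pi * sigma2))
    p = 1.0 / (1.0 + np.exp(-eta))
    w = np.bincount(group_idx, weights=p * (1 - p), minlength=n_groups)
    curv = w + 1.0 / sigma2
    ll_laplace = float(0.5 * n_groups * np.log(2 * np.pi)
                       - 0.5 * np.sum(np.log(curv)))
    return ll_cond + ll_prior + ll_laplace


def _fit_logistic_glmm(
    formula: str, df: pd.DataFrame, group_col: str = "participant_id"
) -> tuple[np.ndarray, np.ndarray, list[str], float, int]:
    """ML fit; returns (beta, cov_beta, names, sigma_u, n_obs)."""
    y_mat, X_mat = patsy.dmatrices(formula, df, return_type="dataframe")
    y = y_mat.to_numpy(dtype=float).ravel()
    X = X_mat.to_numpy(dtype=float)
    names = list(X_mat.columns)
    if y.min() == y.max():
        raise SeparationError(
            "all responses identical: the logistic likelihood is degenerate"
        )
    groups, group_idx = np.unique(df[group_col].to_numpy(), return_inverse=True)
    n_groups = groups.size

    def neg_ll(params):
        return -_glmm_loglik(params, X, y, group_idx, n_groups)

    x0 = np.zeros(X.shape[1] + 1)
    # start fixed effects at the pooled logistic fit for speed/stability
    from statsmodels.api import GLM, families
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pooled = GLM(y, X, family=families.Binomial()).fit()
    x0[:-1] = np.clip(pooled.params, -8, 8)
    x0[-1] = np.log(0.5)
    opt = optimize.minimize(
        neg_ll, x0, method="L-BFGS-B",
        options={"ftol": 1e-13, "gtol": 1e-9, "maxfun": 20000})
    if not np.all(np.isfinite(opt.x)):
        raise RuntimeError("GLMM optimization diverged")
    if np.any(np.abs(opt.x[:-1]) > 15):
        raise SeparationError(
            "fixed-effect estimate diverged: quasi-complete separation"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        H = approx_hess3(opt.x, neg_ll)
    try:
        cov_all = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_all = np.linalg.pinv(H)
    k = X.shape[1]
    return (opt.x[:k], cov_all[:k, :k], names,
            float(np.exp(opt.x[-1])), len(y))


def fit_acc_glmm(results: pd.DataFrame) -> ModelFit:
    """Logistic mixed model accuracy ~ congruence, participant intercept.

    Reports the congruence effect on the log-odds scale (incongruent vs
    congruent) with a Wald z test.
    """
    df = _included_responded(results).copy()
    if df["congruence"].nunique() < 2:
        raise ValueError("need both congruence conditions")
    df["congruence"] = pd.Categorical(
        df["congruence"], categories=["congruent", "incongruent"])
    df["acc"] = df["correct"].astype(int)
    beta, cov, names, sigma_u, n = _fit_logistic_glmm(
        "acc ~ congruence", df)
    i = names.index("congruence[T.incongruent]")
    est, se = float(beta[i]), float(np.sqrt(cov[i, i]))
    z = est / se
    p = float(2 * stats.norm.sf(abs(z)))
    return ModelFit(
        formula="accuracy ~ congruence + (1 | participant), logit link",
        fixed_effects=[(nm, float(b), float(np.sqrt(cov[j, j])))
                       for j, (nm, b) in enumerate(zip(names, beta))],
        random_intercept_sd=sigma_u,
        test=("z(congruence)", float(z), 1.0, float("inf"), p),
        n_obs=n,
        cov_fixed=cov,
        fe_names=names,
    )


def _wald_chi2(beta: np.ndarray, cov: np.ndarray, L: np.ndarray,
               df2: float) -> tuple[float, float, float, float]:
    """Wald test of L beta = 0 reported on the F scale (chi2/q, residual df)."""
    q = L.shape[0]
    est = L @ beta
    V = L @ cov @ L.T
    chi2 = float(est @ np.linalg.solve(V, est))
    f = chi2 / q
    p = float(stats.f.sf(f, q, df2))
    return (f, float(q), float(df2), p)


def fit_caf_glmm(results: pd.DataFrame, n_bins: int = 7) -> ModelFit:
    """Logistic mixed model accuracy ~ congruence x bin (categorical).

    ``results`` must carry a ``bin`` column (septile assignment from the
    distributional module).  Reports Wald tests for the congruence and bin
    main effects and their interaction.
    """
    df = _included_responded(results).copy()
    if "bin" not in df.columns:
        raise ValueError("results must include a 'bin' column")
    cells = df.groupby(["congruence", "bin"]).size()
    expected = 2 * n_bins
    if len(cells) < expected:
        have = set(cells.index)
        missing = [
            (c, b) for c in ("congruent", "incongruent")
            for b in range(1, n_bins + 1) if (c, b) not in have
        ]
        raise ValueError(f"empty congruence x bin cells: {missing}")
    df["congruence"] = pd.Categorical(
        df["congruence"], categories=["congruent", "incongruent"])
    df["bin"] = pd.Categorical(df["bin"], categories=range(1, n_bins + 1))
    df["acc"] = df["correct"].astype(int)
    beta, cov, names, sigma_u, n = _fit_logistic_glmm(
        "acc ~ congruence * bin", df)

    df2 = max(n - len(names) - 1, 1)
    idx_cong = [i for i, nm in enumerate(names)
                if nm.startswith("congruence[") and ":" not in nm]
    idx_bin = [i for i, nm in enumerate(names)
               if nm.startswith("bin[") and ":" not in nm]
    idx_int = [i for i, nm in enumerate(names) if ":" in nm]

    def sel(rows):
        L = np.zeros((len(rows), len(names)))
        for r, i in enumerate(rows):
            L[r, i] = 1.0
        return L

    tests = {
        "congruence": _wald_chi2(beta, cov, sel(idx_cong), df2),
        "bin": _wald_chi2(beta, cov, sel(idx_bin), df2),
        "congruence:bin": _wald_chi2(beta, cov, sel(idx_int), df2),
    }
    inter = tests["congruence:bin"]
    return ModelFit(
        formula="accuracy ~ congruence * bin + (1 | participant), logit link",
        fixed_effects=[(nm, float(b), float(np.sqrt(cov[j, j])))
                       for j, (nm, b) in enumerate(zip(names, beta))],
        random_intercept_sd=sigma_u,
        test=("F(congruence:bin)",) + inter,
        extra_tests={k: v for k, v in tests.items()},
        n_obs=n,
        cov_fixed=cov,
        fe_names=names,
    )


def _max_abs_z_adjust(z: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Single-step adjusted p-values: P(max_j |Z_j| >= |z_k|) under joint normal."""
    k = z.size
    adj = np.empty(k)
    mvn = stats.multivariate_normal(mean=np.zeros(k), cov=corr,
                                    allow_singular=True)
    for i, zi in enumerate(np.abs(z)):
        if not np.isfinite(zi):
            adj[i] = 0.0 if zi > 0 else 1.0
            continue
        rect = float(mvn.cdf(np.full(k, zi), lower_limit=np.full(k, -zi)))
        adj[i] = min(max(1.0 - rect, 0.0), 1.0)
    return adj


def _holm_adjust(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    k = p.size
    adj = np.empty(k)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (k - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj


def posthoc_congruence_by_bin(
    fit: ModelFit, n_bins: int = 7, method: str = "max-z"
) -> list[Contrast]:
    """Congruence contrast within each bin from a fitted CAF model.

    Each contrast is the incongruent-minus-congruent log-odds difference in
    bin k (z-test).  ``method='max-z'`` applies the single-step max-|z|
    adjustment over the family using the joint normal of the contrasts;
    ``method='holm'`` is the deterministic step-down fallback.  Adjusted
    p-values never fall below the raw ones.
    """
    if fit.cov_fixed is None:
        raise ValueError("fit lacks a fixed-effect covariance")
    names = fit.fe_names
    beta = np.array([e for _, e, _ in fit.fixed_effects])
    cong_idx = next(i for i, nm in enumerate(names)
                    if nm.startswith("congruence[") and ":" not in nm)
    L = np.zeros((n_bins, len(names)))
    for b in range(1, n_bins + 1):
        L[b - 1, cong_idx] = 1.0
        if b > 1:
            inter = next(
                (i for i, nm in enumerate(names)
                 if ":" in nm and f"[T.{b}]" in nm), None)
            if inter is None:
                raise ValueError(f"no interaction term for bin {b}")
            L[b - 1, inter] = 1.0
    est = L @ beta
    V = L @ fit.cov_fixed @ L.T
    se = np.sqrt(np.diag(V))
    z = est / se
    p_raw = 2 * stats.norm.sf(np.abs(z))
    if method == "max-z":
        d = np.sqrt(np.diag(V))
        corr = V / np.outer(d, d)
        p_adj = _max_abs_z_adjust(z, corr)
    elif method == "holm":
        p_adj = _holm_adjust(p_raw)
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    p_adj = np.maximum(p_adj, p_raw)
    return [
        Contrast(
            label=f"incongruent - congruent | bin {b}",
            estimate=float(est[b - 1]), se=float(se[b - 1]),
            z_value=float(z[b - 1]), p_value=float(p_raw[b - 1]),
            p_adjusted=float(p_adj[b - 1]),
        )
        for b in range(1, n_bins + 1)
    ]


def fit_delta_lmm(delta_rows: pd.DataFrame) -> ModelFit:
    """Linear mixed model delta ~ bin (categorical), participant intercept.

    Omnibus Wald F for the bin effect with residual-df denominator.
    """
    df = delta_rows.copy()
    n_bins = df["bin"].nunique()
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    df["bin"] = pd.Categorical(df["bin"], categories=sorted(df["bin"].unique()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            "delta_ms ~ bin", groups="participant_id", data=df)
        res = model.fit(reml=True)
    k = len(res.fe_params)
    cov = np.asarray(res.cov_params())[:k, :k]
    beta = res.fe_params.to_numpy()
    L = np.zeros((n_bins - 1, k))
    for r in range(n_bins - 1):
        L[r, r + 1] = 1.0
    df2 = max(len(df) - k - 1, 1)
    f, df1, df2, p = _wald_chi2(beta, cov, L, df2)
    re_var = float(np.asarray(res.cov_re).ravel()[0])
    return ModelFit(
        formula="delta_ms ~ bin + (1 | participant)",
        fixed_effects=[(nm, float(res.params[nm]), float(res.bse[nm]))
                       for nm in res.fe_params.index],
        random_intercept_sd=float(np.sqrt(max(re_var, 0.0))),
        test=("F(bin)", f, df1, df2, p),
        n_obs=len(df),
        singular=re_var < 1e-8,
        cov_fixed=cov,
        fe_names=list(res.fe_params.index),
    )
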