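"""Mixed-effects analysis of plant diversity effects across management regimes.

The central model regresses an annual sward response y (biomass yield, a
forage-quality variable, a quality-adjusted yield, or revenue) on

    y = alpha_M + beta_{DxM} f(D) + beta_{LxM} L + beta_FG FG
        + beta_G G + beta_H H + u_B + u_P + e

with f(D) a diversity transform (default sqrt), one intercept and one
diversity slope per management regime M (cell-means coding, so beta_{DxM}
reads directly as the per-management diversity effect), legume presence L
interacted with management, functional-group number FG and grass / tall-herb
presence as plot covariates, and random intercepts for block (u_B) and for
plot nested in block (u_P).  Residuals may be heteroscedastic across
regimes; inference therefore uses a cluster-robust (plot-level) sandwich
covariance in addition to the model-based one.

Fitting is by REML (reported estimates) through :class:`statsmodels` MixedLM;
information-criterion comparisons between diversity transforms use ML fits
of the same observations.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
import statsmodels.formula.api as smf

__all__ = [
    "DIVERSITY_FORMS",
    "DiversityModel",
    "DiversityResults",
    "SingularDesignError",
    "ConvergenceError",
    "select_diversity_form",
    "legume_robustness",
]


class SingularDesignError(ValueError):
    """The design does not identify the requested model."""


class ConvergenceError(RuntimeError):
    """The mixed-model optimizer failed; carries optimizer diagnostics."""


#: candidate diversity transforms: name -> patsy factor expressions
DIVERSITY_FORMS: dict[str, tuple[str, ...]] = {
    "sqrt": ("np.sqrt(richness)",),
    "linear": ("richness",),
    "linear_squared": ("richness", "I(richness**2)"),
    "log": ("np.log(richness)",),
    "inverse": ("I(1.0 / richness)",),
}

_MANAGEMENTS = (
    "extensive", "less_intensive", "intensive", "highly_intensive",
    "very_highly_intensive",
)


def _cluster_robust_cov(X: np.ndarray, resid: np.ndarray, block: np.ndarray,
                        plot: np.ndarray, s2_block: float, s2_plot: float,
                        s2_resid: float) -> np.ndarray:
    """Plot-clustered sandwich covariance of the GLS fixed effects.

    The marginal covariance V = s2_B Z_B Z_B' + s2_P Z_P Z_P' + s2_e I is
    block-diagonal over blocks (plots are nested in blocks); the bread is
    A = X' V^-1 X and the meat sums outer products of per-plot score
    contributions g_c = (X' V^-1)_c r_c, with the conventional finite-sample
    factor G/(G-1) x (n-1)/(n-k) over the G plot clusters (the correction
    used by standard cluster-robust regression software; tests against this
    covariance use t/F references with G-1 degrees of freedom).
    """
    n, p = X.shape
    A = np.zeros((p, p))
    meat = np.zeros((p, p))
    n_clusters = len(np.unique(plot))
    s2_resid = max(s2_resid, 1e-12)
    for b in np.unique(block):
        idx = np.flatnonzero(block == b)
        Xb, rb, pb = X[idx], resid[idx], plot[idx]
        Zp = (pb[:, None] == np.unique(pb)[None, :]).astype(float)
        V = s2_resid * np.eye(len(idx)) + s2_block + s2_plot * (Zp @ Zp.T)
        c = cho_factor(V, lower=True)
        VinvX = cho_solve(c, Xb)
        A += Xb.T @ VinvX
        W = VinvX.T  # p x n_b, equals X_b' V_b^-1
        for cl in np.unique(pb):
            cidx = pb == cl
            g = W[:, cidx] @ rb[cidx]
            meat += np.outer(g, g)
    Ainv = np.linalg.inv(A)
    factor = (n_clusters / max(n_clusters - 1, 1)) * ((n - 1) / max(n - p, 1))
    return factor * (Ainv @ meat @ Ainv)


class DiversityModel:
    """Diversity-effect mixed model for one annual response variable.

    Parameters
    ----------
    data : DataFrame
        Annual table: one row per sward with the response column and the
        covariates block, plot_id, management, richness, legume_present,
        legume_share, n_functional_groups, grass_present, tall_herb_present.
    response : str
        Column to model (e.g. ``"qa_me"`` or ``"biomass_yield"``).
    diversity_form : str
        One of :data:`DIVERSITY_FORMS` (default ``"sqrt"``).
    legume_term : str
        ``"presence"`` for L x M with L a 0/1 indicator, or ``"sqrt_share"``
        for sqrt(legume share) x M (the robustness variant).
    """

    def __init__(self, data: pd.DataFrame, response: str,
                 diversity_form: str = "sqrt", legume_term: str = "presence"):
        if diversity_form not in DIVERSITY_FORMS:
            raise ValueError(
                f"unknown diversity_form {diversity_form!r}; "
                f"expected one of {sorted(DIVERSITY_FORMS)}"
            )
        if legume_term not in ("presence", "sqrt_share"):
            raise ValueError("legume_term must be 'presence' or 'sqrt_share'")
        required = {
            response, "block", "plot_id", "management", "richness",
            "legume_present", "n_functional_groups", "grass_present",
            "tall_herb_present",
        }
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"annual table lacks columns: {sorted(missing)}")
        if data[list(required)].isna().any().any():
            raise ValueError("missing values in response or covariates")
        present = set(data["management"].unique())
        absent = set(_MANAGEMENTS) - present
        if absent:
            raise SingularDesignError(
                f"management level(s) {sorted(absent)} absent from the data; "
                "per-management slopes are not identified"
            )
        if data.groupby("block")["plot_id"].nunique().min() < 2:
            raise SingularDesignError("each block needs at least 2 plots")

        df = data.copy()
        df["_legume_x"] = (
            df["legume_present"].astype(float)
            if legume_term == "presence"
            else np.sqrt(df["legume_share"].astype(float))
        )
        for col in ("n_functional_groups", "grass_present", "tall_herb_present"):
            df[col] = df[col].astype(float)
        self.data = df
        self.response = response
        self.diversity_form = diversity_form
        self.legume_term = legume_term
        self.dropped_terms: list[str] = []
        self.formula = self._build_formula()

    def _build_formula(self) -> str:
        df = self.data
        terms = ["0", "C(management)"]
        terms += [f"C(management):{t}" for t in DIVERSITY_FORMS[self.diversity_form]]
        # covariate terms degenerate to zero/constant columns in some designs
        # (e.g. no legumes anywhere); drop them to keep the design full rank
        optional = [
            ("C(management):_legume_x", df["_legume_x"].nunique() > 1 or df["_legume_x"].iloc[0] != 0),
            ("n_functional_groups", df["n_functional_groups"].nunique() > 1),
            ("grass_present", df["grass_present"].nunique() > 1),
            ("tall_herb_present", df["tall_herb_present"].nunique() > 1),
        ]
        for term, keep in optional:
            if keep:
                terms.append(term)
            else:
                self.dropped_terms.append(term)
        return f"Q('{self.response}') ~ " + " + ".join(terms)

    def fit(self, reml: bool = True, method=("lbfgs", "powell"),
            maxiter: int = 1000) -> "DiversityResults":
        """Fit by REML (default) or ML; returns a :class:`DiversityResults`."""
        df = self.data
        # exact-fit degenerate case (noise-free data): the GLS solution is the
        # OLS solution and the variance components are all zero, but the
        # mixed-model likelihood is unbounded -- handle directly
        y0, X0 = patsy.dmatrices(self.formula, df, return_type="dataframe")
        beta0, _, rank, _ = np.linalg.lstsq(X0.to_numpy(), y0.to_numpy().ravel(), rcond=None)
        if rank < X0.shape[1]:
            raise SingularDesignError(
                f"design matrix is rank deficient ({rank} < {X0.shape[1]}); "
                "check for collinear covariates"
            )
        resid0 = y0.to_numpy().ravel() - X0.to_numpy() @ beta0
        yvar = float(np.var(y0.to_numpy())) or 1.0
        if float(np.mean(resid0**2)) <= 1e-12 * yvar:
            return self._exact_fit_results(X0, y0, beta0, reml)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(
                self.formula, data=df, groups="block", re_formula="1",
                vc_formula={"plot": "0 + C(plot_id)"},
            )
            res = md.fit(reml=reml, method=list(method), maxiter=maxiter)
        if not res.converged:
            raise ConvergenceError(
                f"mixed-model fit did not converge for response "
                f"{self.response!r} (form {self.diversity_form!r}); "
                f"optimizer state: {getattr(res, 'mle_retvals', None)}"
            )
        fe = res.fe_params
        sigma2_block = float(np.asarray(res.cov_re)[0, 0])
        sigma2_plot = float(np.asarray(res.vcomp).ravel()[0])
        sigma2_resid = float(res.scale)
        X = np.asarray(md.exog, dtype=float)
        resid = np.asarray(md.endog, dtype=float) - X @ fe.to_numpy()
        cov_rob = _cluster_robust_cov(
            X, resid, df["block"].to_numpy(), df["plot_id"].to_numpy(),
            sigma2_block, sigma2_plot, sigma2_resid,
        )
        k = len(fe) + 3  # fixed effects + two variance components + scale
        llf = float(res.llf)
        return DiversityResults(
            model=self,
            fe_params=fe,
            cov_model=pd.DataFrame(
                np.asarray(res.cov_params())[: len(fe), : len(fe)],
                index=fe.index, columns=fe.index,
            ),
            cov_robust=pd.DataFrame(cov_rob, index=fe.index, columns=fe.index),
            sigma2_block=sigma2_block,
            sigma2_plot=sigma2_plot,
            sigma2_resid=sigma2_resid,
            llf=llf,
            aic=-2.0 * llf + 2.0 * k,
            bic=-2.0 * llf + k * np.log(len(df)),
            n_obs=len(df),
            n_clusters=int(df["plot_id"].nunique()),
            reml=reml,
            converged=True,
            design_info=X0.design_info,
        )

    def _exact_fit_results(self, X0, y0, beta0, reml) -> "DiversityResults":
        fe = pd.Series(beta0, index=X0.columns)
        zero = pd.DataFrame(
            np.zeros((len(fe), len(fe))), index=fe.index, columns=fe.index
        )
        return DiversityResults(
            model=self, fe_params=fe, cov_model=zero, cov_robust=zero.copy(),
            sigma2_block=0.0, sigma2_plot=0.0, sigma2_resid=0.0,
            llf=np.inf, aic=-np.inf, bic=-np.inf, n_obs=len(y0),
            n_clusters=int(self.data["plot_id"].nunique()),
            reml=reml, converged=True, design_info=X0.design_info,
            exact_fit=True,
        )


@dataclass
class DiversityResults:
    """Fitted diversity mixed model: estimates, covariances and inference."""

    model: DiversityModel
    fe_params: pd.Series
    cov_model: pd.DataFrame
    cov_robust: pd.DataFrame
    sigma2_block: float
    sigma2_plot: float
    sigma2_resid: float
    llf: float
    aic: float
    bic: float
    n_obs: int
    n_clusters: int
    reml: bool
    converged: bool
    design_info: object = None
    exact_fit: bool = False

    # -- coefficient access ------------------------------------------------

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_model)), index=self.fe_params.index)

    @property
    def bse_robust(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_robust)), index=self.fe_params.index)

    def _slope_names(self) -> dict[str, str]:
        dterm = DIVERSITY_FORMS[self.model.diversity_form][0]
        out = {}
        for m in _MANAGEMENTS:
            matches = [
                name for name in self.fe_params.index
                if f"[{m}]" in name
                and name.split(":")[-1].replace(" ", "") == dterm.replace(" ", "")
            ]
            if len(matches) != 1:
                raise RuntimeError(f"cannot locate diversity slope for {m!r}: {matches}")
            out[m] = matches[0]
        return out

    @property
    def diversity_slopes(self) -> pd.Series:
        """Per-management diversity slope (leading diversity term)."""
        names = self._slope_names()
        return pd.Series(
            {m: float(self.fe_params[n]) for m, n in names.items()}, name="slope"
        )

    # -- inference ---------------------------------------------------------

    def effect_table(self, n_tests: int = 1, robust: bool = True) -> pd.DataFrame:
        """Per-management diversity effects with Bonferroni-adjusted stars.

        ``n_tests`` is the size of the test family the response belongs to
        (6 for the forage-quality family, 1 for biomass yield).  Stars mark
        significance at the 5%/1%/0.1% family levels, i.e. raw p below
        level / n_tests.
        """
        if n_tests < 1:
            raise ValueError("n_tests must be >= 1")
        names = self._slope_names()
        cov = self.cov_robust if robust else self.cov_model
        rows = []
        for m, name in names.items():
            est = float(self.fe_params[name])
            se = float(np.sqrt(cov.loc[name, name]))
            t = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
            # t reference with G - 1 df, G the number of plot clusters
            df_t = max(self.n_clusters - 1, 1)
            p = 2.0 * stats.t.sf(abs(t), df_t) if np.isfinite(t) else 0.0
            stars = "".join(
                "*" for level in (0.05, 0.01, 0.001) if p < level / n_tests
            )
            rows.append(
                {"management": m, "slope": est, "se_robust": se, "t": t,
                 "p_raw": p, "significance": stars, "n_tests": n_tests}
            )
        return pd.DataFrame(rows)

    def pairwise_wald(self, robust: bool = True) -> pd.DataFrame:
        """Wald tests of slope equality for all 10 management pairs."""
        names = self._slope_names()
        cov = (self.cov_robust if robust else self.cov_model)
        rows = []
        for m1, m2 in itertools.combinations(_MANAGEMENTS, 2):
            n1, n2 = names[m1], names[m2]
            diff = float(self.fe_params[n1] - self.fe_params[n2])
            var = float(
                cov.loc[n1, n1] + cov.loc[n2, n2] - 2.0 * cov.loc[n1, n2]
            )
            stat = diff**2 / var if var > 0 else np.inf
            # F(1, G-1) reference, the finite-sample convention matching the
            # cluster-robust covariance correction
            df2 = max(self.n_clusters - 1, 1)
            rows.append(
                {"management_1": m1, "management_2": m2, "difference": diff,
                 "wald_stat": stat, "p_value": float(stats.f.sf(stat, 1, df2))}
            )
        return pd.DataFrame(rows)

    # -- prediction --------------------------------------------------------

    def predict_grid(self, d_grid, managements=None,
                     average_managements: bool = False) -> pd.DataFrame:
        """Fixed-effects predictions over a diversity grid.

        Covariates (legume term, functional groups, grass/tall-herb
        presence) are held at their observed sample means; because the model
        is linear in them, this equals averaging predictions over the
        observed covariate distribution.  Random effects are set to zero.
        """
        d_grid = np.atleast_1d(np.asarray(d_grid, dtype=float))
        if np.any(d_grid < 1) or np.any(d_grid > 60):
            warnings.warn(
                "diversity grid extends outside the experimental range [1, 60]; "
                "predictions are extrapolations", UserWarning, stacklevel=2,
            )
        managements = list(managements or _MANAGEMENTS)
        df = self.model.data
        new = pd.DataFrame(
            [
                {
                    "richness": d,
                    "management": m,
                    "_legume_x": df["_legume_x"].mean(),
                    "n_functional_groups": df["n_functional_groups"].mean(),
                    "grass_present": df["grass_present"].mean(),
                    "tall_herb_present": df["tall_herb_present"].mean(),
                }
                for d in d_grid
                for m in managements
            ]
        )
        (X,) = patsy.build_design_matrices([self.design_info], new)
        new["predicted"] = np.asarray(X) @ self.fe_params.to_numpy()
        out = new[["richness", "management", "predicted"]]
        if average_managements:
            out = (
                out.groupby("richness", as_index=False)["predicted"].mean()
                .assign(management="average")
            )
        return out

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        lines = [
            f"Diversity mixed model: {self.model.response} "
            f"~ {self.model.diversity_form} diversity x management",
            f"n_obs={self.n_obs}  method={'REML' if self.reml else 'ML'}"
            + ("  [exact fit: noise-free data]" if self.exact_fit else ""),
            f"variance components: block={self.sigma2_block:.3f}  "
            f"plot={self.sigma2_plot:.3f}  residual={self.sigma2_resid:.3f}",
            f"logLik={self.llf:.2f}  AIC={self.aic:.2f}  BIC={self.bic:.2f}",
            "",
            "coefficients (robust SE in brackets):",
        ]
        for name in self.fe_params.index:
            lines.append(
                f"  {name:<55s} {self.fe_params[name]:>12.4f} "
                f"[{self.bse_robust[name]:.4f}]"
            )
        if self.model.dropped_terms:
            lines.append(f"dropped degenerate terms: {self.model.dropped_terms}")
        return "\n".join(lines)


def select_diversity_form(data: pd.DataFrame, response: str,
                          forms=None, legume_term: str = "presence") -> pd.DataFrame:
    """Fit each candidate diversity transform by ML and rank by AIC and BIC.

    All candidates use the identical observation set; a candidate that fails
    to fit is reported with the error message rather than aborting the race.
    """
    forms = list(forms or DIVERSITY_FORMS)
    rows = []
    for form in forms:
        try:
            res = DiversityModel(
                data, response, diversity_form=form, legume_term=legume_term
            ).fit(reml=False)
            rows.append(
                {"form": form, "n_obs": res.n_obs, "llf": res.llf,
                 "aic": res.aic, "bic": res.bic, "error": ""}
            )
        except Exception as exc:  # propagate per-form failure as a row
            rows.append(
                {"form": form, "n_obs": np.nan, "llf": np.nan,
                 "aic": np.nan, "bic": np.nan, "error": str(exc)}
            )
    out = pd.DataFrame(rows)
    out["rank_aic"] = out["aic"].rank(method="min")
    out["rank_bic"] = out["bic"].rank(method="min")
    return out.sort_values("bic").reset_index(drop=True)


def legume_robustness(data: pd.DataFrame, response: str,
                      diversity_form: str = "sqrt") -> pd.DataFrame:
    """Side-by-side diversity slopes under the two legume parameterizations.

    Refits the model with sqrt(legume share) x management replacing the
    legume-presence interaction and returns the per-management slopes from
    both variants.
    """
    res_presence = DiversityModel(
        data, response, diversity_form, legume_term="presence"
    ).fit()
    res_share = DiversityModel(
        data, response, diversity_form, legume_term="sqrt_share"
    ).fit()
    return pd.DataFrame(
        {
            "slope_legume_presence": res_presence.diversity_slopes,
            "se_legume_presence": [
                res_presence.bse_robust[n]
                for n in res_presence._slope_names().values()
            ],
            "slope_legume_sqrt_share": res_share.diversity_slopes,
            "se_legume_sqrt_share": [
                res_share.bse_robust[n]
                for n in res_share._slope_names().values()
            ],
        }
    )
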