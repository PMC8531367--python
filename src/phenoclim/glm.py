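"""Binomial-logit GLMs with polynomial photoperiod and climate interactions.

The model family: flower presence/absence regressed on z-scaled growing
degree days (GDD), average precipitation and daylength, with daylength
optionally entering as an orthogonal second-degree polynomial and with
up-to-three-way interactions among the three drivers. Fitting is by
iteratively reweighted least squares (IRLS, i.e. Newton scoring on the
Bernoulli log-likelihood); candidate models are screened by variance
inflation factors and ranked by AIC or AICc.

Organised statsmodels-style: :class:`BinomialLogit` is the model object,
:meth:`BinomialLogit.fit` returns a :class:`BinomialLogitResults` carrying
estimates, standard errors, information criteria and a ``summary()`` table.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .basis import OrthoPolyBasis

__all__ = [
    "ModelSpec",
    "BinomialLogit",
    "BinomialLogitResults",
    "fit_logistic_irls",
    "build_design",
    "compute_vif",
    "enumerate_candidates",
    "select_model",
    "SelectionResult",
    "PerfectSeparationWarning",
]


class PerfectSeparationWarning(UserWarning):
    """The likelihood is unbounded: some coefficients diverge."""


# --------------------------------------------------------------------------
# model specifications and design matrices
# --------------------------------------------------------------------------

MAIN_EFFECTS = ("gdd", "avg_precip", "daylength")

_LABELS = {"gdd": "GDD", "avg_precip": "Average precipitation", "daylength": "Daylength"}


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: which mains, daylength degree, interaction order.

    ``interaction_order`` 0 means main effects only, 2 adds all pairwise
    products among the included drivers, 3 adds the full three-way product
    (which requires all three mains). Daylength of degree 2 enters through
    its two orthogonal polynomial columns; interactions then distribute
    over both columns, which is how the 12-term full model arises:
    intercept + 3 + 2 extra poly + 5 pairwise + 2 three-way.
    """

    mains: tuple = MAIN_EFFECTS
    daylength_degree: int = 1
    interaction_order: int = 0

    def __post_init__(self):
        if not set(self.mains) <= set(MAIN_EFFECTS):
            raise ValueError(f"unknown main effects in {self.mains}")
        if self.daylength_degree not in (1, 2):
            raise ValueError("daylength_degree must be 1 or 2")
        if self.interaction_order not in (0, 2, 3):
            raise ValueError("interaction_order must be 0, 2 or 3")
        if self.interaction_order == 3 and set(self.mains) != set(MAIN_EFFECTS):
            raise ValueError("three-way interaction requires all three main effects")

    @property
    def n_params(self) -> int:
        k = 1 + len(self.mains)
        if "daylength" in self.mains and self.daylength_degree == 2:
            k += 1
        if self.interaction_order >= 2:
            groups = self._term_groups()
            k += sum(
                len(a) * len(b) for a, b in itertools.combinations(groups, 2)
            )
        if self.interaction_order == 3:
            groups = self._term_groups()
            k += int(np.prod([len(g) for g in groups]))
        return k

    def _term_groups(self):
        """Each driver's design columns (daylength may span two)."""
        groups = []
        for m in self.mains:
            if m == "daylength" and self.daylength_degree == 2:
                groups.append(["Poly1 (daylength)", "Poly2 (daylength)"])
            else:
                groups.append([_LABELS[m]])
        return groups

    @property
    def label(self) -> str:
        dl = "poly2(daylength)" if self.daylength_degree == 2 else "daylength"
        inter = {0: "no interactions", 2: "pairwise", 3: "three-way"}[self.interaction_order]
        return f"mains({len(self.mains)}) + {dl} + {inter}"

    def to_dict(self) -> dict:
        return {
            "mains": list(self.mains),
            "daylength_degree": self.daylength_degree,
            "interaction_order": self.interaction_order,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(tuple(d["mains"]), int(d["daylength_degree"]), int(d["interaction_order"]))


def enumerate_candidates() -> list:
    """The candidate ladder: linear vs polynomial daylength × interaction order.

    Six specifications, from main effects only up to the full three-way
    interaction with second-degree daylength, ordered by parameter count.
    """
    specs = [
        ModelSpec(MAIN_EFFECTS, d, o) for d in (1, 2) for o in (0, 2, 3)
    ]
    return sorted(specs, key=lambda s: s.n_params)


def build_design(rows: pd.DataFrame, spec: ModelSpec, poly_basis: OrthoPolyBasis | None = None):
    """Design matrix and term names for a candidate model.

    ``rows`` must carry ``scaled_gdd``, ``scaled_avg_precip`` and
    ``scaled_daylength`` (training-set scaling). For degree-2 daylength a
    fitted :class:`~phenoclim.basis.OrthoPolyBasis` must be supplied; it is
    applied, never refitted, so new data are projected onto the training
    basis. Interaction columns are elementwise products of the main
    columns they involve.
    """
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(rows))}
    groups = []
    for m in spec.mains:
        if m == "daylength" and spec.daylength_degree == 2:
            if poly_basis is None or poly_basis.alpha is None:
                raise ValueError("degree-2 daylength requires a fitted OrthoPolyBasis")
            P = poly_basis.transform(rows["scaled_daylength"].to_numpy(float))
            cols["Poly1 (daylength)"] = P[:, 0]
            cols["Poly2 (daylength)"] = P[:, 1]
            groups.append(["Poly1 (daylength)", "Poly2 (daylength)"])
        else:
            cols[_LABELS[m]] = rows[f"scaled_{m}"].to_numpy(float)
            groups.append([_LABELS[m]])
    if spec.interaction_order >= 2:
        for ga, gb in itertools.combinations(groups, 2):
            for a in ga:
                for b in gb:
                    cols[f"{a}:{b}"] = cols[a] * cols[b]
    if spec.interaction_order == 3:
        for combo in itertools.product(*groups):
            name = ":".join(combo)
            v = np.ones(len(rows))
            for c in combo:
                v = v * cols[c]
            cols[name] = v
    names = list(cols)
    X = np.column_stack([cols[n] for n in names])
    return X, names


# --------------------------------------------------------------------------
# IRLS fitting
# --------------------------------------------------------------------------


class BinomialLogit:
    """Bernoulli GLM with logit link, fitted by IRLS.

    Parameters
    ----------
    endog : array of {0,1}
    exog : (n, k) design matrix, full column rank, including the intercept
    names : optional term names for the summary table
    """

    def __init__(self, endog, exog, names=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim == 1:
            self.exog = self.exog[:, None]
        if self.endog.shape[0] != self.exog.shape[0]:
            raise ValueError("endog and exog lengths differ")
        if not np.all(np.isin(self.endog, (0.0, 1.0))):
            raise ValueError("response must be binary 0/1")
        if np.linalg.matrix_rank(self.exog) < self.exog.shape[1]:
            raise ValueError("design matrix is rank deficient")
        self.names = list(names) if names is not None else [
            f"x{j}" for j in range(self.exog.shape[1])
        ]

    @classmethod
    def from_dataframe(cls, rows: pd.DataFrame, spec: ModelSpec, poly_basis=None, response="y"):
        X, names = build_design(rows, spec, poly_basis)
        return cls(rows[response].to_numpy(float), X, names)

    def loglike(self, params) -> float:
        eta = self.exog @ params
        # numerically stable: log p and log(1-p) via logaddexp
        return float(np.sum(self.endog * eta - np.logaddexp(0.0, eta)))

    def fit(self, max_iter: int = 50, tol: float = 1e-8) -> "BinomialLogitResults":
        """Newton/IRLS maximum likelihood.

        Convergence is declared when the largest score (gradient)
        component falls below ``tol``. Perfect separation shows up as
        diverging coefficients with collapsing working weights; it is
        flagged with a warning and ``converged=False`` rather than
        silently reporting huge estimates.
        """
        X, y = self.exog, self.endog
        n, k = X.shape
        beta = np.zeros(k)
        converged = False
        separated = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            eta = X @ beta
            mu = expit(eta)
            score = X.T @ (y - mu)
            if np.max(np.abs(score)) < tol:
                converged = True
                break
            w = mu * (1.0 - mu)
            if np.max(w) < 1e-10 or np.max(np.abs(beta)) > 1e3:
                separated = True
                break
            XtWX = (X * w[:, None]).T @ X
            try:
                step = np.linalg.solve(XtWX, score)
            except np.linalg.LinAlgError:
                separated = True
                break
            # step-halving keeps the log-likelihood non-decreasing
            ll_old = self.loglike(beta)
            factor = 1.0
            for _ in range(30):
                cand = beta + factor * step
                if self.loglike(cand) >= ll_old - 1e-12:
                    break
                factor /= 2.0
            beta = beta + factor * step
        mu_fit = expit(X @ beta)
        if k > 1 and np.all(np.abs(y - mu_fit) < 1e-3):
            # fitted probabilities indistinguishable from the response:
            # the MLE does not exist and the coefficients are diverging
            separated = True
            converged = False
        if not converged and (separated or np.max(np.abs(beta)) > 1e2):
            warnings.warn(
                "possible perfect separation: coefficients diverging, "
                "fit flagged as non-converged",
                PerfectSeparationWarning,
            )
        mu = expit(X @ beta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        fisher = (X * w[:, None]).T @ X
        cov = np.linalg.pinv(fisher)
        return BinomialLogitResults(self, beta, cov, converged, n_iter)


class BinomialLogitResults:
    """Fit results: estimates, SEs, information criteria, pseudo-R²."""

    def __init__(self, model: BinomialLogit, params, cov_params, converged, n_iter):
        self.model = model
        self.params = np.asarray(params, float)
        self.cov_params = np.asarray(cov_params, float)
        self.converged = bool(converged)
        self.n_iter = int(n_iter)
        self.nobs = model.endog.shape[0]
        self.k = model.exog.shape[1]
        self.llf = model.loglike(self.params)
        ybar = float(np.mean(model.endog))
        if 0.0 < ybar < 1.0:
            self.llnull = self.nobs * (ybar * np.log(ybar) + (1 - ybar) * np.log(1 - ybar))
        else:
            self.llnull = 0.0

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k

    @property
    def aicc(self) -> float:
        n, k = self.nobs, self.k
        if n - k - 1 <= 0:
            return np.inf
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)

    @property
    def prsquared_mcfadden(self) -> float:
        return 1.0 - self.llf / self.llnull if self.llnull != 0 else np.nan

    @property
    def prsquared_nagelkerke(self) -> float:
        n = self.nobs
        cox_snell = 1.0 - np.exp(2.0 * (self.llnull - self.llf) / n)
        denom = 1.0 - np.exp(2.0 * self.llnull / n)
        return cox_snell / denom if denom != 0 else np.nan

    def predict(self, exog=None) -> np.ndarray:
        X = self.model.exog if exog is None else np.asarray(exog, float)
        return expit(X @ self.params)

    def coefficient_table(self) -> pd.DataFrame:
        """Estimate ± SE with z, p and significance stars (* p<0.05, ** p<0.01)."""
        stars = np.where(self.pvalues < 0.01, "**", np.where(self.pvalues < 0.05, "*", ""))
        return pd.DataFrame(
            {
                "term": self.model.names,
                "estimate": self.params,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
                "sig": stars,
            }
        )

    def summary(self) -> str:
        tab = self.coefficient_table()
        lines = [
            "Binomial logit GLM (IRLS)",
            f"  n = {self.nobs}, k = {self.k}, converged = {self.converged} "
            f"({self.n_iter} iterations)",
            f"  log-likelihood = {self.llf:.3f}, AIC = {self.aic:.2f}, AICc = {self.aicc:.2f}",
            f"  pseudo-R2: McFadden = {self.prsquared_mcfadden:.3f}, "
            f"Nagelkerke = {self.prsquared_nagelkerke:.3f}",
            "",
            f"  {'term':<48}{'estimate':>12}{'SE':>10}{'z':>8}{'p':>10}",
        ]
        for _, r in tab.iterrows():
            lines.append(
                f"  {r['term']:<48}{r['estimate']:>12.3f}{r['se']:>10.3f}"
                f"{r['z']:>8.2f}{r['p']:>10.3g} {r['sig']}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "names": self.model.names,
            "params": self.params.tolist(),
            "bse": self.bse.tolist(),
            "llf": self.llf,
            "aic": self.aic,
            "aicc": self.aicc,
            "n": int(self.nobs),
            "k": int(self.k),
            "pseudo_r2_mcfadden": self.prsquared_mcfadden,
            "pseudo_r2_nagelkerke": self.prsquared_nagelkerke,
            "converged": self.converged,
            "iterations": self.n_iter,
        }


def fit_logistic_irls(X, y, names=None, max_iter: int = 50, tol: float = 1e-8):
    """Functional entry point: fit a binomial-logit GLM by IRLS."""
    return BinomialLogit(y, X, names=names).fit(max_iter=max_iter, tol=tol)


# --------------------------------------------------------------------------
# collinearity screening and model selection
# --------------------------------------------------------------------------


def compute_vif(X, names=None) -> pd.DataFrame:
    """Variance inflation factor per design column (intercept excluded).

    VIF_j = 1/(1 − R²_j), with R²_j from regressing column j on all other
    columns plus an intercept. An exactly collinear column reports +inf.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least two columns to compute VIFs")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    out = []
    n = X.shape[0]
    for j in range(X.shape[1]):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        if ss_tot <= 0:
            vif = np.inf
        else:
            r2 = 1.0 - np.sum(resid**2) / ss_tot
            vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        out.append(vif)
    return pd.DataFrame({"term": names, "vif": out})


@dataclass
class SelectionResult:
    """Ranked candidates with ΔIC and Akaike weights, plus screening info."""

    table: pd.DataFrame
    best_spec: ModelSpec
    best_results: BinomialLogitResults
    screened_out: list = field(default_factory=list)
    criterion: str = "aicc"


def select_model(
    candidates,
    rows: pd.DataFrame,
    poly_basis: OrthoPolyBasis | None = None,
    criterion: str = "aicc",
    vif_threshold: float = 5.0,
    response: str = "y",
) -> SelectionResult:
    """Screen candidates by VIF, fit survivors, rank by AIC or AICc.

    Akaike weights w_i = exp(−Δ_i/2) / Σ_j exp(−Δ_j/2) are computed over
    the retained candidates; the best model has ΔIC = 0 by construction.
    Ranking breaks ties by parameter count, so the result does not depend
    on the order candidates are supplied in.

    The VIF screen is applied to a candidate's main-effect columns (the
    drivers, with daylength expanded to its polynomial columns). Product
    terms of mean-zero predictors inflate per-column VIFs mechanically
    even when the underlying drivers are near-orthogonal — the reason
    generalized VIF exists — so screening the interaction columns
    themselves would veto every interaction model regardless of how clean
    the drivers are. Screening the drivers keeps the check meaningful:
    a candidate whose raw predictors are collinear still fails.
    """
    if criterion not in ("aic", "aicc"):
        raise ValueError("criterion must be 'aic' or 'aicc'")
    fitted, screened_out = [], []
    for spec in candidates:
        X, names = build_design(rows, spec, poly_basis)
        mains_spec = ModelSpec(spec.mains, spec.daylength_degree, 0)
        Xm, mnames = build_design(rows, mains_spec, poly_basis)
        if Xm.shape[1] > 2:
            vifs = compute_vif(Xm[:, 1:], mnames[1:])
            max_vif = float(vifs["vif"].max())
        else:
            max_vif = 1.0
        if max_vif > vif_threshold:
            screened_out.append({"spec": spec, "max_vif": max_vif})
            continue
        res = BinomialLogit(rows[response].to_numpy(float), X, names).fit()
        fitted.append((spec, res, max_vif))
    if not fitted:
        detail = "; ".join(f"{s['spec'].label}: max VIF {s['max_vif']:.1f}" for s in screened_out)
        raise ValueError(f"all candidate models failed the VIF <= {vif_threshold} screen ({detail})")

    ics = np.array([getattr(r, criterion) for _, r, _ in fitted])
    order = np.lexsort((np.array([s.n_params for s, _, _ in fitted]), ics))
    ics_sorted = ics[order]
    delta = ics_sorted - ics_sorted[0]
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    table = pd.DataFrame(
        {
            "spec": [fitted[i][0].label for i in order],
            "k": [fitted[i][0].n_params for i in order],
            criterion: ics_sorted,
            f"delta_{criterion}": delta,
            "akaike_weight": w,
            "max_vif": [fitted[i][2] for i in order],
        }
    )
    best_spec, best_res, _ = fitted[order[0]]
    return SelectionResult(table, best_spec, best_res, screened_out, criterion)
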