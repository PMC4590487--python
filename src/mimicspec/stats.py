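"""Mixed-model and logistic inference for the behavioural analyses.

Two estimators, exposed statsmodels-style (``Model.from_formula(...).fit()``
returning a results object with ``params`` / ``bse`` / ``pvalues`` /
``summary()``):

:class:`RandomInterceptModel`
    Gaussian linear mixed model with a single random intercept, estimated by
    REML.  The variance ratio ``λ = σ²_group / σ²_resid`` is profiled out by
    scalar optimization; fixed effects come from GLS at the optimum.  Fixed
    effects are tested with t statistics on containment degrees of freedom
    ``n − rank(X) − (n_groups − 1)``, which reproduces the paired t-test
    exactly on balanced two-condition within-group designs.
:class:`BinaryLogitModel`
    Maximum-likelihood logistic regression via iteratively reweighted least
    squares, with Wald Z tests.

On top sit the model-selection conventions of the analysis: backward
elimination of non-significant terms at ``p > 0.05`` with the focal
treatment protected, and reference-category rotation to obtain all pairwise
contrasts of a factor.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats as sps

__all__ = [
    "RandomInterceptModel",
    "RandomInterceptResults",
    "BinaryLogitModel",
    "BinaryLogitResults",
    "fit_lmm",
    "fit_logistic",
    "backward_eliminate",
    "rotate_reference",
    "run_paper_models",
    "SeparationWarning",
    "categorical_term",
]


class SeparationWarning(UserWarning):
    """Raised when a logistic fit shows (quasi-)complete separation."""


def _build_design(formula: str, data: pd.DataFrame):
    y, X = patsy.dmatrices(formula, data, return_type="dataframe",
                           NA_action="raise")
    return np.asarray(y).ravel(), X


def categorical_term(column: str, reference: str | None = None) -> str:
    """Patsy term string for a categorical column, optionally re-referenced."""
    if reference is None:
        return f"C({column})"
    return f"C({column}, Treatment(reference={reference!r}))"


def _term_slices(X: pd.DataFrame) -> dict[str, slice]:
    info = X.design_info
    return {t: info.term_name_slices[t] for t in info.term_names}


# ---------------------------------------------------------------------------
# results containers


class _ResultsBase:
    """Shared coefficient-table behaviour for both estimators."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = self._crit(alpha)
        return pd.DataFrame({"lower": self.params - q * self.bse,
                             "upper": self.params + q * self.bse})

    def term_pvalue(self, term: str) -> float:
        """Joint Wald test of all coefficients belonging to one term."""
        sl = self.term_names[term]
        b = self.params.iloc[sl].to_numpy()
        V = self.cov_params[sl, sl]
        w = float(b @ np.linalg.solve(V, b))
        q = b.size
        return self._joint_p(w, q)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.params, "se": self.bse,
            self._stat_name: self.tvalues, "p": self.pvalues,
        })

    def summary(self) -> str:
        lines = [self._header(), "-" * 72,
                 self.to_frame().to_string(float_format=lambda v: f"{v:.4f}")]
        lines.append("-" * 72)
        lines.append(self._footer())
        return "\n".join(lines)


@dataclass
class RandomInterceptResults(_ResultsBase):
    """REML fit of a single-random-intercept Gaussian mixed model."""

    params: pd.Series
    bse: pd.Series
    cov_params: np.ndarray
    sigma_resid: float
    sigma_group: float
    df_resid: float
    n_obs: int
    n_groups: int
    llf: float
    formula: str
    term_names: dict[str, slice]
    boundary: bool = False
    fittedvalues: np.ndarray | None = field(default=None, repr=False)

    _stat_name = "t"

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * sps.t.sf(np.abs(self.tvalues), self.df_resid),
            index=self.params.index)

    @property
    def random_effect_sd(self) -> float:
        return self.sigma_group

    def _crit(self, alpha):
        return sps.t.ppf(1 - alpha / 2, self.df_resid)

    def _joint_p(self, w, q):
        return float(sps.f.sf(w / q, q, self.df_resid))

    def _header(self):
        return (f"Random-intercept LMM (REML)   {self.formula}\n"
                f"n = {self.n_obs}, groups = {self.n_groups}, "
                f"t df = {self.df_resid:.0f}")

    def _footer(self):
        note = "  [boundary: group variance -> 0]" if self.boundary else ""
        return (f"sigma_group = {self.sigma_group:.4f}   "
                f"sigma_resid = {self.sigma_resid:.4f}   "
                f"REML loglik = {self.llf:.3f}{note}")


@dataclass
class BinaryLogitResults(_ResultsBase):
    """Maximum-likelihood logistic regression fit."""

    params: pd.Series
    bse: pd.Series
    cov_params: np.ndarray
    llf: float
    n_obs: int
    converged: bool
    formula: str
    term_names: dict[str, slice]
    degenerate: bool = False
    fittedvalues: np.ndarray | None = field(default=None, repr=False)

    _stat_name = "z"

    @property
    def tvalues(self) -> pd.Series:  # Wald Z, named tvalues for API symmetry
        return self.params / self.bse

    zvalues = tvalues

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * sps.norm.sf(np.abs(self.tvalues)),
                         index=self.params.index)

    @property
    def deviance(self) -> float:
        return -2.0 * self.llf

    random_effect_sd = None

    def _crit(self, alpha):
        return sps.norm.ppf(1 - alpha / 2)

    def _joint_p(self, w, q):
        return float(sps.chi2.sf(w, q))

    def _header(self):
        return (f"Logistic regression (IRLS)    {self.formula}\n"
                f"n = {self.n_obs}, converged = {self.converged}")

    def _footer(self):
        note = "  [degenerate: constant response]" if self.degenerate else ""
        return f"loglik = {self.llf:.3f}{note}"


# ---------------------------------------------------------------------------
# random-intercept LMM


class RandomInterceptModel:
    """Gaussian linear mixed model with one random intercept per group."""

    def __init__(self, endog: np.ndarray, exog: pd.DataFrame,
                 groups: np.ndarray, formula: str = ""):
        self.y = np.asarray(endog, dtype=float)
        self.X = exog
        self.formula = formula or "y ~ X"
        codes, self.group_levels = pd.factorize(np.asarray(groups))
        if len(self.group_levels) < 2:
            raise ValueError("need at least 2 groups for a random intercept")
        self.codes = codes
        Xa = np.asarray(exog, dtype=float)
        rank = np.linalg.matrix_rank(Xa)
        if rank < Xa.shape[1]:
            aliased = self._aliased_columns(Xa)
            raise ValueError(f"singular fixed-effect design; aliased "
                             f"columns: {aliased}")

    def _aliased_columns(self, Xa):
        _, r = np.linalg.qr(Xa)
        diag = np.abs(np.diag(r))
        return [self.X.columns[i] for i in range(Xa.shape[1])
                if diag[i] < 1e-10 * diag.max()]

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame,
                     groups: str) -> "RandomInterceptModel":
        y, X = _build_design(formula, data)
        return cls(y, X, data[groups].to_numpy(), formula=formula)

    # -- profiled REML machinery ------------------------------------------

    def _group_stats(self):
        Xa = np.asarray(self.X, dtype=float)
        y = self.y
        g = self.codes
        n_groups = len(self.group_levels)
        p = Xa.shape[1]
        XtX = Xa.T @ Xa
        Xty = Xa.T @ y
        yty = float(y @ y)
        sX = np.zeros((n_groups, p))
        sy = np.zeros(n_groups)
        np.add.at(sX, g, Xa)
        np.add.at(sy, g, y)
        n_i = np.bincount(g, minlength=n_groups).astype(float)
        return Xa, XtX, Xty, yty, sX, sy, n_i

    def _profile(self, lam, stats_tuple):
        """GLS quantities and REML criterion at a fixed variance ratio."""
        Xa, XtX, Xty, yty, sX, sy, n_i = stats_tuple
        n, p = Xa.shape
        c = lam / (1.0 + lam * n_i)  # per-group Woodbury weight
        A = XtX - (sX * c[:, None]).T @ sX
        b = Xty - sX.T @ (c * sy)
        q = yty - float(c @ sy ** 2)
        beta = np.linalg.solve(A, b)
        rss = q - float(beta @ (2 * b - A @ beta))
        rss = max(rss, 1e-300)
        sigma2 = rss / (n - p)
        logdet_v = float(np.sum(np.log1p(lam * n_i)))
        sign, logdet_a = np.linalg.slogdet(A)
        # REML log-likelihood up to an additive constant
        llf = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma2) + 1)
                      + logdet_v + logdet_a)
        return beta, sigma2, A, llf

    def fit(self) -> RandomInterceptResults:
        stats_tuple = self._group_stats()
        n, p = np.asarray(self.X).shape
        n_groups = len(self.group_levels)

        def neg_llf(theta):
            return -self._profile(np.exp(theta), stats_tuple)[3]

        res = optimize.minimize_scalar(neg_llf, bounds=(-14.0, 14.0),
                                       method="bounded",
                                       options={"xatol": 1e-8})
        lam = float(np.exp(res.x))
        llf_hat = -res.fun
        llf0 = self._profile(0.0, stats_tuple)[3]
        boundary = llf0 >= llf_hat - 1e-9
        if boundary:
            lam = 0.0
            warnings.warn("group variance estimated at zero; the mixed "
                          "model reduces to OLS", UserWarning, stacklevel=2)
        beta, sigma2, A, llf = self._profile(lam, stats_tuple)
        cov = sigma2 * np.linalg.inv(A)
        df = max(n - p - (n_groups - 1), 1)
        idx = self.X.columns
        fitted = np.asarray(self.X) @ beta
        term_names = (_term_slices(self.X)
                      if hasattr(self.X, "design_info")
                      else {c: slice(i, i + 1) for i, c in enumerate(idx)})
        return RandomInterceptResults(
            params=pd.Series(beta, index=idx),
            bse=pd.Series(np.sqrt(np.diag(cov)), index=idx),
            cov_params=cov, sigma_resid=float(np.sqrt(sigma2)),
            sigma_group=float(np.sqrt(lam * sigma2)), df_resid=float(df),
            n_obs=n, n_groups=n_groups, llf=float(llf), formula=self.formula,
            term_names=term_names, boundary=boundary, fittedvalues=fitted)


# ---------------------------------------------------------------------------
# logistic regression


class BinaryLogitModel:
    """Binary logistic regression fitted by IRLS (Newton-Raphson)."""

    def __init__(self, endog, exog: pd.DataFrame, formula: str = ""):
        self.y = np.asarray(endog, dtype=float)
        if not np.all(np.isin(self.y, (0.0, 1.0))):
            raise ValueError("response must be binary 0/1")
        self.X = exog
        self.formula = formula or "y ~ X"
        if self.y.size <= np.asarray(exog).shape[1]:
            raise ValueError("need more observations than model terms")

    @classmethod
    def from_formula(cls, formula: str,
                     data: pd.DataFrame) -> "BinaryLogitModel":
        y, X = _build_design(formula, data)
        return cls(y, X, formula=formula)

    def fit(self, maxiter: int = 100, tol: float = 1e-10
            ) -> BinaryLogitResults:
        Xa = np.asarray(self.X, dtype=float)
        y = self.y
        n, p = Xa.shape
        degenerate = y.min() == y.max()
        beta = np.zeros(p)
        if degenerate:
            warnings.warn("constant response: intercept-only degenerate "
                          "fit", UserWarning, stacklevel=2)
        converged = False
        for _ in range(maxiter):
            eta = np.clip(Xa @ beta, -30, 30)
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1 - mu)
            W = np.maximum(w, 1e-10)
            H = Xa.T @ (Xa * W[:, None])
            grad = Xa.T @ (y - mu)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                break
            beta = beta + step
            if np.max(np.abs(step)) < tol:
                converged = True
                break
        eta = np.clip(Xa @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        llf = float(np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))
        if not degenerate:
            resolved = (mu > 1 - 1e-6) | (mu < 1e-6)
            if (not converged) or resolved.all() or np.abs(beta).max() > 15:
                worst = self.X.columns[int(np.argmax(np.abs(beta)))]
                warnings.warn(
                    f"possible complete separation (term {worst!r}); "
                    "coefficients may be unbounded", SeparationWarning,
                    stacklevel=2)
        w = np.maximum(mu * (1 - mu), 1e-10)
        cov = np.linalg.inv(Xa.T @ (Xa * w[:, None]))
        idx = self.X.columns
        term_names = (_term_slices(self.X)
                      if hasattr(self.X, "design_info")
                      else {c: slice(i, i + 1) for i, c in enumerate(idx)})
        return BinaryLogitResults(
            params=pd.Series(beta, index=idx),
            bse=pd.Series(np.sqrt(np.diag(cov)), index=idx),
            cov_params=cov, llf=llf, n_obs=n, converged=converged,
            formula=self.formula, term_names=term_names,
            degenerate=degenerate, fittedvalues=mu)


# ---------------------------------------------------------------------------
# operation-style wrappers


def fit_lmm(data: pd.DataFrame, response: str, fixed_terms: list[str],
            group: str) -> RandomInterceptResults:
    """Fit a random-intercept LMM from term strings (patsy syntax)."""
    rhs = " + ".join(fixed_terms) if fixed_terms else "1"
    return RandomInterceptModel.from_formula(f"{response} ~ {rhs}", data,
                                             groups=group).fit()


def fit_logistic(data: pd.DataFrame, response: str,
                 terms: list[str]) -> BinaryLogitResults:
    """Fit a binary logistic regression from term strings."""
    rhs = " + ".join(terms) if terms else "1"
    return BinaryLogitModel.from_formula(f"{response} ~ {rhs}", data).fit()


def backward_eliminate(fit_fn, data: pd.DataFrame, response: str,
                       full_terms: list[str],
                       protected: tuple[str, ...] = (),
                       alpha: float = 0.05):
    """Iteratively drop the least significant removable term.

    At each step the term (factor terms tested jointly) with the largest
    Wald p-value above ``alpha`` is removed and the model refitted, until
    every remaining removable term is significant or only protected terms
    remain.  Returns ``(final_results, full_results, trace)`` where the
    trace lists each elimination step — mirroring a full-vs-final model
    report.
    """
    terms = list(full_terms)
    full_res = fit_fn(data, response, terms)
    res = full_res
    trace: list[dict] = []
    while True:
        removable = [t for t in terms if t not in protected]
        if not removable:
            break
        pvals = {t: res.term_pvalue(t) for t in removable}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] <= alpha:
            break
        terms = [t for t in terms if t != worst]
        trace.append({"dropped": worst, "p": pvals[worst],
                      "remaining": tuple(terms)})
        res = fit_fn(data, response, terms)
    return res, full_res, trace


_TLEVEL = re.compile(r"\[T\.(.+)\]$")


def rotate_reference(fit_fn, data: pd.DataFrame, response: str,
                     terms: list[str], factor: str) -> pd.DataFrame:
    """All pairwise contrasts of a factor by rotating its reference level.

    Refits the model once per reference level and collects the k(k−1)/2
    unique level contrasts.  Because each refit is a reparameterization of
    the same model, fitted values are unchanged and contrast(A, B) =
    −contrast(B, A) holds by construction; contrasts are reported once with
    ``level_a`` < ``level_b`` and sign convention A − B... specifically the
    estimate is the effect of ``level_a`` relative to ``level_b``.
    """
    levels = sorted(pd.unique(data[factor].astype(str)))
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")
    base_terms = [t for t in terms if factor not in t]
    rows = {}
    for ref in levels:
        fterms = [categorical_term(factor, ref)] + base_terms
        res = fit_fn(data, response, fterms)
        for name, est in res.params.items():
            if factor not in name:
                continue
            m = _TLEVEL.search(name)
            if not m:
                continue
            lvl = m.group(1)
            a, b = sorted((lvl, ref))
            if (a, b) in rows:
                continue
            sign = 1.0 if lvl == a else -1.0
            i = list(res.params.index).index(name)
            stat = float(res.tvalues.iloc[i])
            rows[(a, b)] = {
                "level_a": a, "level_b": b,
                "estimate": sign * float(est),
                "se": float(res.bse.iloc[i]),
                "stat": sign * stat,
                "p": float(res.pvalues.iloc[i]),
            }
    return pd.DataFrame(list(rows.values()))


# ---------------------------------------------------------------------------
# the three study analyses


@dataclass
class ModelReport:
    """Full model, eliminated final model, trace and pairwise contrasts."""

    response: str
    full: _ResultsBase
    final: _ResultsBase
    trace: list[dict]
    contrasts: pd.DataFrame


def _lmm_factory(group):
    def fit_fn(data, response, terms):
        return fit_lmm(data, response, terms, group)
    return fit_fn


def _logit_factory():
    def fit_fn(data, response, terms):
        return fit_logistic(data, response, terms)
    return fit_fn


def run_paper_models(plumage_table: pd.DataFrame | None = None,
                     trial_table: pd.DataFrame | None = None,
                     rejection_table: pd.DataFrame | None = None,
                     alpha: float = 0.05) -> dict[str, ModelReport]:
    """Run the three inference stages of the mimicry analysis.

    * Plumage LMMs: per-species mean colour / luminance / log-pattern
      difference ~ taxon group, random intercept on body region.
    * Aggression LMMs: alarm calls and mobbing seconds ~ model type (with
      presentation order, model replicate and nest stage in the full
      model), random intercept on breeding pair; backward elimination
      protects model type.
    * Rejection logit: accept/reject ~ model type + egg-difference
      covariates, eliminated down at ``alpha`` with model type protected.

    Every stage reports full and final fits, the elimination trace and the
    pairwise treatment contrasts obtained by reference rotation.
    """
    out: dict[str, ModelReport] = {}

    if plumage_table is not None:
        fit_fn = _lmm_factory("region")
        for resp in ("colour_jnd", "luminance_jnd", "log_s_diff"):
            if resp not in plumage_table:
                continue
            terms = [categorical_term("taxon_group")]
            final, full, trace = backward_eliminate(
                fit_fn, plumage_table, resp, terms,
                protected=tuple(terms), alpha=alpha)
            contrasts = rotate_reference(fit_fn, plumage_table, resp, terms,
                                         "taxon_group")
            out[f"plumage_{resp}"] = ModelReport(resp, full, final, trace,
                                                 contrasts)

    if trial_table is not None:
        fit_fn = _lmm_factory("pair_id")
        full_terms = [categorical_term("model_type"), "presentation_order",
                      categorical_term("model_replicate"),
                      categorical_term("nest_stage")]
        for resp in ("alarm_calls", "mobbing_seconds"):
            final, full, trace = backward_eliminate(
                fit_fn, trial_table, resp, full_terms,
                protected=(categorical_term("model_type"),), alpha=alpha)
            final_terms = (list(trace[-1]["remaining"]) if trace
                           else list(full_terms))
            contrasts = rotate_reference(fit_fn, trial_table, resp,
                                         final_terms, "model_type")
            out[f"aggression_{resp}"] = ModelReport(resp, full, final, trace,
                                                    contrasts)

    if rejection_table is not None:
        fit_fn = _logit_factory()
        covariates = [c for c in ("colour_jnd", "luminance_jnd",
                                  "pattern_diff", "shape_diff",
                                  "volume_diff")
                      if c in rejection_table]
        full_terms = [categorical_term("model_type")] + covariates
        final, full, trace = backward_eliminate(
            fit_fn, rejection_table, "rejected", full_terms,
            protected=(categorical_term("model_type"),), alpha=alpha)
        final_terms = (list(trace[-1]["remaining"]) if trace
                       else list(full_terms))
        contrasts = rotate_reference(fit_fn, rejection_table, "rejected",
                                     final_terms, "model_type")
        out["rejection"] = ModelReport("rejected", full, final, trace,
                                       contrasts)
    return out
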