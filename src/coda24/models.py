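"""Association models between the movement-behavior composition and child
outcomes.

Two designs are supported, mirroring a two-timepoint cohort analysis:

* cross-sectional: ordinary least squares of an outcome on (ilr1, ilr2, age,
  sex) using one record per child (first timepoint preferred);
* longitudinal: a random-intercept linear mixed model on all available
  records, estimated by maximum likelihood so that full-vs-null
  likelihood-ratio tests of the two ilr coordinates are valid.

The composition enters through ilr pivot coordinates under a selectable
rotation. Fit statistics (log-likelihood, R-squared, F and chi-square tests)
are invariant to the rotation; only the ilr1/ilr2 coefficient values change
meaning, which is exactly what the three-rotation coefficient table exploits.

Estimators follow the scikit-learn protocol (``fit``/``predict``,
``get_params``, trailing-underscore fitted attributes); the module-level
functions operating on tidy record tables are thin wrappers around them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .composition import Rotation, ilr_array

__all__ = [
    "OUTCOME_COLUMNS",
    "IlrTransformer",
    "CompositionalLinearModel",
    "CompositionalMixedModel",
    "ModelFit",
    "CompositionTest",
    "cohen_label",
    "select_cross_sectional",
    "fit_cross_sectional",
    "fit_longitudinal",
    "composition_test",
    "influence_exclude_refit",
    "rotation_table",
]

#: Outcome columns recognized in record tables.
OUTCOME_COLUMNS = ("se_raw", "se_scaled", "gm_raw", "gm_scaled", "zbmi")

_MINUTE_COLS = ["pa_min", "sb_min", "sleep_min"]
_PARAM_NAMES = ("intercept", "ilr1", "ilr2", "age_months", "sex")
_NULL_PARAM_NAMES = ("intercept", "age_months", "sex")


class RankDeficientDesign(ValueError):
    """A design matrix column is constant or collinear."""


class IlrTransformer(TransformerMixin, BaseEstimator):
    """Stateless transformer: minutes (n, 3) in (PA, SB, sleep) order ->
    ilr pivot coordinates (n, 2) under ``rotation``.

    Accepts plain arrays or DataFrames carrying pa_min/sb_min/sleep_min
    columns, so it can open an sklearn pipeline on tidy record tables.
    """

    def __init__(self, rotation: Rotation | str = Rotation.PA):
        self.rotation = rotation

    def fit(self, X, y=None):
        X = self._minutes(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_in_")
        return ilr_array(self._minutes(X), Rotation(self.rotation))

    @staticmethod
    def _minutes(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            cols = _MINUTE_COLS if set(_MINUTE_COLS) <= set(X.columns) else X.columns
            X = X[list(cols)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("expected (n, 3) minutes in (PA, SB, sleep) order")
        return X

    def get_feature_names_out(self, input_features=None):
        return np.array(["ilr1", "ilr2"])


def _design(
    X: pd.DataFrame | np.ndarray, rotation: Rotation, include_composition: bool
) -> tuple[np.ndarray, list[str]]:
    """Build [1, ilr1, ilr2, age, sex] (or the covariate-only null design)
    from a table with columns pa_min, sb_min, sleep_min, age_months, sex."""
    if isinstance(X, pd.DataFrame):
        arr = X[_MINUTE_COLS + ["age_months", "sex"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 5:
            raise ValueError(
                "expected columns (pa_min, sb_min, sleep_min, age_months, sex)"
            )
    if not np.all(np.isfinite(arr)):
        raise ValueError("design inputs contain missing or non-finite values")
    z = ilr_array(arr[:, :3], rotation)
    cols: list[np.ndarray] = [np.ones(len(arr))]
    names = ["intercept"]
    if include_composition:
        cols += [z[:, 0], z[:, 1]]
        names += ["ilr1", "ilr2"]
    cols += [arr[:, 3], arr[:, 4]]
    names += ["age_months", "sex"]
    design = np.column_stack(cols)
    # fail loudly on constant/collinear columns rather than silently dropping
    for j, name in enumerate(names[1:], start=1):
        if np.ptp(design[:, j]) == 0:
            raise RankDeficientDesign(f"design column {name!r} is constant")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise RankDeficientDesign("design matrix is rank deficient (collinear columns)")
    return design, names


@dataclass
class ModelFit:
    """A fitted association model plus everything downstream stages need.

    ``params``/``cov_params`` are indexed by term name; for mixed fits
    ``tau2`` is the random-intercept variance and ``r2_marginal`` /
    ``r2_conditional`` are the Nakagawa–Schielzeth variance partitions.
    """

    model_class: Literal["linear", "mixed"]
    rotation: Rotation
    params: pd.Series
    cov_params: pd.DataFrame
    llf: float
    sigma2: float
    nobs: int
    n_children: int
    tau2: float | None = None
    df_resid: float | None = None
    rsquared: float | None = None
    r2_marginal: float | None = None
    r2_conditional: float | None = None
    # raw fitting data, retained so tests/exclusions can refit consistently
    design: np.ndarray | None = field(default=None, repr=False)
    y: np.ndarray | None = field(default=None, repr=False)
    groups: np.ndarray | None = field(default=None, repr=False)
    index: np.ndarray | None = field(default=None, repr=False)
    term_names: tuple[str, ...] = ()

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.design @ self.params.to_numpy()

    @property
    def resid(self) -> np.ndarray:
        """Marginal residuals y - X beta (population-level)."""
        return self.y - self.fittedvalues

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov_params.to_numpy()))
        if self.model_class == "linear":
            q = st.t.ppf(0.5 + level / 2, self.df_resid)
        else:
            q = st.norm.ppf(0.5 + level / 2)
        est = self.params.to_numpy()
        return pd.DataFrame(
            {"low": est - q * se, "high": est + q * se}, index=self.params.index
        )

    def pvalues(self) -> pd.Series:
        se = np.sqrt(np.diag(self.cov_params.to_numpy()))
        tstat = self.params.to_numpy() / se
        if self.model_class == "linear":
            p = 2 * st.t.sf(np.abs(tstat), self.df_resid)
        else:
            p = 2 * st.norm.sf(np.abs(tstat))
        return pd.Series(p, index=self.params.index)


class CompositionalLinearModel(RegressorMixin, BaseEstimator):
    """OLS of a continuous outcome on (ilr1, ilr2, age, sex) with intercept.

    Parameters
    ----------
    rotation : which behavior is the ilr1 reference. The fit statistics do
        not depend on it; coefficient interpretation does.
    include_composition : set False for the covariates-only null model used
        by the composition likelihood-ratio/F test.
    """

    def __init__(
        self,
        rotation: Rotation | str = Rotation.PA,
        include_composition: bool = True,
    ):
        self.rotation = rotation
        self.include_composition = include_composition

    def fit(self, X, y, groups: Sequence | None = None):
        rotation = Rotation(self.rotation)
        design, names = _design(X, rotation, self.include_composition)
        y = np.asarray(y, dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("outcome contains missing or non-finite values")
        res = sm.OLS(y, design).fit()
        self.result_ = res
        self.term_names_ = tuple(names)
        self.coef_ = res.params[1:]
        self.intercept_ = res.params[0]
        n_children = len(pd.unique(np.asarray(groups))) if groups is not None else len(y)
        self.fit_ = ModelFit(
            model_class="linear",
            rotation=rotation,
            params=pd.Series(res.params, index=names),
            cov_params=pd.DataFrame(res.cov_params(), index=names, columns=names),
            llf=float(res.llf),
            sigma2=float(res.ssr / res.nobs),  # ML variance, matches llf
            nobs=int(res.nobs),
            n_children=n_children,
            df_resid=float(res.df_resid),
            rsquared=float(res.rsquared),
            design=design,
            y=y,
            groups=None if groups is None else np.asarray(groups),
            term_names=tuple(names),
        )
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "fit_")
        design, _ = _design(X, Rotation(self.rotation), self.include_composition)
        return design @ self.fit_.params.to_numpy()


class CompositionalMixedModel(BaseEstimator):
    """Random-intercept linear mixed model, maximum-likelihood estimated.

    ``fit(X, y, groups)`` groups repeated records by child. ML (not REML) is
    used throughout so that full-vs-null likelihood-ratio tests on fixed
    effects are valid. Children observed at a single timepoint are retained;
    with no repeated measures at all the random-intercept variance sits at
    the boundary (0) and a warning is emitted.
    """

    def __init__(
        self,
        rotation: Rotation | str = Rotation.PA,
        include_composition: bool = True,
    ):
        self.rotation = rotation
        self.include_composition = include_composition

    def fit(self, X, y, groups):
        rotation = Rotation(self.rotation)
        design, names = _design(X, rotation, self.include_composition)
        y = np.asarray(y, dtype=float)
        groups = np.asarray(groups)
        if not np.all(np.isfinite(y)):
            raise ValueError("outcome contains missing or non-finite values")
        if pd.Series(groups).value_counts().max() == 1:
            warnings.warn(
                "all children have a single record; random-intercept variance "
                "is not identified and will sit at the boundary 0",
                stacklevel=2,
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, design, groups=groups)
            res = None
            for method in (None, "powell", "cg"):
                try:
                    kw = {} if method is None else {"method": method}
                    res = model.fit(reml=False, **kw)
                    break
                except np.linalg.LinAlgError:
                    continue
            if res is None:  # pragma: no cover - last-resort failure
                raise RuntimeError("mixed-model optimization failed")
        self.result_ = res
        self.term_names_ = tuple(names)
        fe = np.asarray(res.fe_params)
        cov_fe = np.asarray(res.cov_params())[: len(names), : len(names)]
        tau2 = float(np.asarray(res.cov_re).ravel()[0])
        sigma2 = float(res.scale)
        fitted_fixed = design @ fe
        var_f = float(np.var(fitted_fixed))
        denom = var_f + tau2 + sigma2
        self.fit_ = ModelFit(
            model_class="mixed",
            rotation=rotation,
            params=pd.Series(fe, index=names),
            cov_params=pd.DataFrame(cov_fe, index=names, columns=names),
            llf=float(res.llf),
            sigma2=sigma2,
            tau2=tau2,
            nobs=len(y),
            n_children=len(pd.unique(groups)),
            r2_marginal=var_f / denom,
            r2_conditional=(var_f + tau2) / denom,
            design=design,
            y=y,
            groups=groups,
            term_names=tuple(names),
        )
        return self

    def predict(self, X) -> np.ndarray:
        """Population-level prediction (fixed effects only)."""
        check_is_fitted(self, "fit_")
        design, _ = _design(X, Rotation(self.rotation), self.include_composition)
        return design @ self.fit_.params.to_numpy()


# ---------------------------------------------------------------------------
# record-table front ends


def _complete_records(records: pd.DataFrame, outcome: str) -> pd.DataFrame:
    if outcome not in records.columns:
        raise KeyError(f"outcome column {outcome!r} not in records")
    needed = _MINUTE_COLS + ["age_months", "sex", outcome]
    return records.dropna(subset=needed)


def select_cross_sectional(records: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """One record per child with complete data: first timepoint when
    available, otherwise the second."""
    complete = _complete_records(records, outcome)
    complete = complete.sort_values(["child_id", "timepoint"], kind="stable")
    return complete.groupby("child_id", sort=True).head(1)


def fit_cross_sectional(
    records: pd.DataFrame,
    outcome: str,
    rotation: Rotation | str = Rotation.PA,
    include_composition: bool = True,
    min_records: int = 10,
) -> ModelFit:
    """OLS association model on the cross-sectional record selection."""
    data = select_cross_sectional(records, outcome)
    if len(data) < min_records:
        raise ValueError(
            f"only {len(data)} complete records for {outcome!r}; "
            f"need at least {min_records}"
        )
    est = CompositionalLinearModel(rotation, include_composition).fit(
        data, data[outcome].to_numpy(), groups=data["child_id"].to_numpy()
    )
    est.fit_.index = data.index.to_numpy()
    return est.fit_


def fit_longitudinal(
    records: pd.DataFrame,
    outcome: str,
    rotation: Rotation | str = Rotation.PA,
    include_composition: bool = True,
) -> ModelFit:
    """Random-intercept model on every record with complete data (children
    contribute one or two timepoints)."""
    data = _complete_records(records, outcome)
    if data.empty:
        raise ValueError(f"no complete records for outcome {outcome!r}")
    est = CompositionalMixedModel(rotation, include_composition).fit(
        data, data[outcome].to_numpy(), groups=data["child_id"].to_numpy()
    )
    est.fit_.index = data.index.to_numpy()
    return est.fit_


# ---------------------------------------------------------------------------
# composition test


@dataclass(frozen=True)
class CompositionTest:
    """Joint test of the two ilr coordinates: full vs covariates-only model."""

    kind: Literal["F", "chi2"]
    statistic: float
    df: tuple[float, float] | int
    pvalue: float
    r2_delta: float
    cohen: str
    r2_marginal: float | None = None
    r2_conditional: float | None = None


def cohen_label(r2_delta: float) -> str:
    """Cohen's interpretation bands for an explained-variance change;
    boundary values take the upper class."""
    x = max(float(r2_delta), 0.0)
    if x < 0.02:
        return "very small"
    if x < 0.13:
        return "small"
    if x <= 0.26:
        return "medium"
    return "large"


def _refit_null(full: ModelFit) -> ModelFit:
    """Refit the covariates-only model on exactly the full model's rows."""
    keep = [i for i, t in enumerate(full.term_names) if t not in ("ilr1", "ilr2")]
    design = full.design[:, keep]
    names = [full.term_names[i] for i in keep]
    if full.model_class == "linear":
        res = sm.OLS(full.y, design).fit()
        return ModelFit(
            model_class="linear",
            rotation=full.rotation,
            params=pd.Series(res.params, index=names),
            cov_params=pd.DataFrame(res.cov_params(), index=names, columns=names),
            llf=float(res.llf),
            sigma2=float(res.ssr / res.nobs),
            nobs=int(res.nobs),
            n_children=full.n_children,
            df_resid=float(res.df_resid),
            rsquared=float(res.rsquared),
            design=design,
            y=full.y,
            groups=full.groups,
            term_names=tuple(names),
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MixedLM(full.y, design, groups=full.groups).fit(reml=False)
    tau2 = float(np.asarray(res.cov_re).ravel()[0])
    sigma2 = float(res.scale)
    fitted_fixed = design @ np.asarray(res.fe_params)
    var_f = float(np.var(fitted_fixed))
    denom = var_f + tau2 + sigma2
    return ModelFit(
        model_class="mixed",
        rotation=full.rotation,
        params=pd.Series(np.asarray(res.fe_params), index=names),
        cov_params=pd.DataFrame(
            np.asarray(res.cov_params())[: len(names), : len(names)],
            index=names,
            columns=names,
        ),
        llf=float(res.llf),
        sigma2=sigma2,
        tau2=tau2,
        nobs=full.nobs,
        n_children=full.n_children,
        r2_marginal=var_f / denom,
        r2_conditional=(var_f + tau2) / denom,
        design=design,
        y=full.y,
        groups=full.groups,
        term_names=tuple(names),
    )


def composition_test(full: ModelFit, null: ModelFit | None = None) -> CompositionTest:
    """Test whether the two ilr coordinates jointly improve on the
    covariates-only model.

    Linear fits use the partial F test (2 numerator df) with
    ``r2_delta = R2_full - R2_null``; mixed fits use the 2-df chi-square
    likelihood-ratio test on ML log-likelihoods with ``r2_delta`` taken as
    the change in marginal R-squared, alongside the full model's
    marginal/conditional R-squared.
    """
    if "ilr1" not in full.term_names:
        raise ValueError("full model must include the ilr coordinates")
    if null is None:
        null = _refit_null(full)
    if null.nobs != full.nobs or null.model_class != full.model_class:
        raise ValueError(
            "null model must be fit on the same observations with the same "
            "estimation method; pass null=None to refit it consistently"
        )
    if "ilr1" in null.term_names:
        raise ValueError("null model must exclude the ilr coordinates")
    if full.model_class == "linear":
        rss_full = float(np.sum(full.resid**2))
        rss_null = float(np.sum(null.resid**2))
        df_den = full.df_resid
        fstat = max((rss_null - rss_full) / 2.0, 0.0) / (rss_full / df_den)
        p = float(st.f.sf(fstat, 2, df_den))
        r2d = full.rsquared - null.rsquared
        return CompositionTest(
            kind="F",
            statistic=float(fstat),
            df=(2.0, float(df_den)),
            pvalue=p,
            r2_delta=float(r2d),
            cohen=cohen_label(r2d),
        )
    lrt = max(2.0 * (full.llf - null.llf), 0.0)
    p = float(st.chi2.sf(lrt, 2))
    r2d = float(full.r2_marginal - null.r2_marginal)
    return CompositionTest(
        kind="chi2",
        statistic=float(lrt),
        df=2,
        pvalue=p,
        r2_delta=r2d,
        cohen=cohen_label(r2d),
        r2_marginal=full.r2_marginal,
        r2_conditional=full.r2_conditional,
    )


# ---------------------------------------------------------------------------
# influence diagnostics


def _whitening_blocks(groups: np.ndarray, tau2: float, sigma2: float) -> np.ndarray:
    """Per-observation whitening transform W with W V W' = I for the
    random-intercept covariance V = sigma2 I + tau2 J within each group.

    Returns a dense (n, n) matrix; cohort sizes here are a few hundred rows,
    so dense is fine and keeps the algebra transparent.
    """
    n = len(groups)
    W = np.zeros((n, n))
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        m = len(idx)
        a, b = sigma2, tau2
        # eigendecomposition of V_g: (a + m b) on the mean direction, a elsewhere
        P = np.full((m, m), 1.0 / m)
        Wg = (np.eye(m) - P) / np.sqrt(a) + P / np.sqrt(a + m * b)
        W[np.ix_(idx, idx)] = Wg
    return W


def influence_diagnostics(fit: ModelFit) -> pd.DataFrame:
    """Cook's distance and studentized residuals per observation.

    Linear fits use the standard OLS formulas (externally studentized
    residuals). Mixed fits use the fixed-effects analogues computed on the
    GLS-whitened problem: whiten X and y by the estimated marginal covariance,
    then apply the OLS influence formulas — Cook's distance then measures each
    observation's influence on the fixed effects, and the studentized
    residual is the scaled conditional-covariance-adjusted residual.
    """
    if fit.model_class == "linear":
        X, y = fit.design, fit.y
    else:
        W = _whitening_blocks(fit.groups, fit.tau2, fit.sigma2)
        X, y = W @ fit.design, W @ fit.y
    n, p = X.shape
    res = sm.OLS(y, X).fit()
    infl = res.get_influence()
    cooks = infl.cooks_distance[0]
    student = infl.resid_studentized_external
    return pd.DataFrame(
        {"cooks_d": cooks, "studentized": student},
        index=fit.index if fit.index is not None else np.arange(n),
    )


def influence_exclude_refit(
    fit: ModelFit,
    records: pd.DataFrame,
    outcome: str,
    cooks_multiple: float = 4.0,
    resid_bound: float = 2.0,
) -> tuple[np.ndarray, ModelFit]:
    """Single-pass influence exclusion: drop observations with Cook's
    distance > 4/n AND |studentized residual| > 2, then refit once.

    Returns the excluded record index labels and the refit; with nothing
    excluded the refit is the original fit object.
    """
    diag = influence_diagnostics(fit)
    cutoff = cooks_multiple / fit.nobs
    mask = (diag["cooks_d"] > cutoff) & (diag["studentized"].abs() > resid_bound)
    excluded = diag.index[mask].to_numpy()
    if len(excluded) == 0:
        return excluded, fit
    kept = records.loc[[i for i in fit.index if i not in set(excluded)]]
    if fit.model_class == "linear":
        refit = fit_cross_sectional(kept, outcome, fit.rotation)
    else:
        refit = fit_longitudinal(kept, outcome, fit.rotation)
    return excluded, refit


# ---------------------------------------------------------------------------
# per-rotation coefficient table


def rotation_table(
    records: pd.DataFrame,
    outcome: str,
    analysis: Literal["cross_sectional", "longitudinal"] = "cross_sectional",
    level: float = 0.95,
) -> pd.DataFrame:
    """ilr1 coefficient, CI and p-value for each reference behavior.

    One model per rotation; ilr1 then reads as "the reference behavior
    relative to the remaining two". The shared log-likelihood across rows is
    included as a cross-check of rotation invariance.
    """
    fitter = fit_cross_sectional if analysis == "cross_sectional" else fit_longitudinal
    rows = []
    for rot in Rotation:
        f = fitter(records, outcome, rot)
        ci = f.conf_int(level).loc["ilr1"]
        rows.append(
            {
                "reference": rot.value,
                "beta_ilr1": f.params["ilr1"],
                "ci_low": ci["low"],
                "ci_high": ci["high"],
                "pvalue": f.pvalues()["ilr1"],
                "llf": f.llf,
                "n": f.nobs,
            }
        )
    return pd.DataFrame(rows)
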