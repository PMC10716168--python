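"""Longitudinal developmental trajectory models.

Every network property y observed per scan is modelled with a linear mixed
model carrying a subject-level random intercept and random age slope:

    y_ij = b0 + u_i + (b_age + v_i) * age_ij + b_sex sex_i + b_tbv tbv_ij
           + b_centre centre_i + eps_ij

with a quadratic variant adding fixed and random age^2 terms and an
interaction variant adding a fixed age-by-sex term.  Models are fitted by
maximum likelihood (not REML) so AIC is comparable across fixed-effect
structures.  Age is mean-centered internally for conditioning; the reported
age slope is on the original scale.

``TrajectoryLMM`` is an sklearn-style estimator; ``fit_lmm`` and
``fit_slope_map`` are thin functional wrappers used by the pipeline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .io import Cohort, RegionTable
from .metrics import nodal_metrics

logger = logging.getLogger(__name__)

MODEL_KINDS = ("linear", "quadratic", "interaction")
#: tie-break order for AIC selection: simpler model wins
_COMPLEXITY = {"linear": 0, "interaction": 1, "quadratic": 2}


@dataclass
class TrajectoryFit:
    """Summary of one mixed-model fit for a single response."""

    model_kind: str
    betas: dict
    beta_age: float
    t_age: float
    p_age: float
    ci_age: tuple
    aic: float
    loglik: float
    random_variances: dict
    residual_variance: float
    n_obs: int
    n_subjects: int
    random_structure: str  # 'intercept+slope' (+'+quad') or 'intercept' fallback

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "betas": self.betas,
            "beta_age": self.beta_age,
            "t_age": self.t_age,
            "p_age": self.p_age,
            "ci_age": list(self.ci_age),
            "aic": self.aic,
            "loglik": self.loglik,
            "random_variances": self.random_variances,
            "residual_variance": self.residual_variance,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "random_structure": self.random_structure,
        }


@dataclass
class SlopeMap:
    """Per-region standardized developmental slope with Bonferroni p."""

    beta_age: np.ndarray
    t: np.ndarray
    p: np.ndarray
    p_bonf: np.ndarray
    significant: np.ndarray
    metric: str = ""

    def to_frame(self, regions: RegionTable | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "region": np.arange(len(self.beta_age)) if regions is None else regions.ids,
                "beta_age": self.beta_age,
                "t": self.t,
                "p": self.p,
                "p_bonf": self.p_bonf,
                "significant": self.significant,
            }
        )
        return df


def _design(data: pd.DataFrame, model_kind: str, extra_covariates=()) -> tuple:
    """Fixed-effect design matrix, column names, age center and sex coding."""
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind '{model_kind}'")
    age = data["age"].to_numpy(float)
    center = float(age.mean())
    age_c = age - center
    sex_levels = sorted(data["sex"].astype(str).unique())
    sex = (data["sex"].astype(str) == sex_levels[-1]).to_numpy(float) if len(sex_levels) > 1 else np.zeros(len(data))
    cols = {"intercept": np.ones(len(data)), "age": age_c}
    if model_kind == "quadratic":
        cols["age2"] = age_c**2
    cols["sex"] = sex
    if model_kind == "interaction":
        cols["age_x_sex"] = age_c * sex
    # centre and standardize continuous covariates for conditioning;
    # coefficients are mapped back to the original scale after the fit
    scales = {}
    tbv = data["tbv"].to_numpy(float)
    sd_tbv = tbv.std(ddof=0) or 1.0
    cols["tbv"] = (tbv - tbv.mean()) / sd_tbv
    scales["tbv"] = sd_tbv
    centre_levels = sorted(data["centre"].astype(str).unique())
    for lev in centre_levels[1:]:  # first level is the reference
        cols[f"centre[{lev}]"] = (data["centre"].astype(str) == lev).to_numpy(float)
    for name in extra_covariates:
        v = data[name].to_numpy(float)
        sd = v.std(ddof=0) or 1.0
        cols[name] = (v - v.mean()) / sd
        scales[name] = sd
    X = np.column_stack(list(cols.values()))
    return X, list(cols.keys()), center, scales


class TrajectoryLMM(BaseEstimator):
    """Mixed-effect developmental trajectory model (sklearn-style).

    Parameters
    ----------
    model_kind : {'linear', 'quadratic', 'interaction'}
        Fixed-effect structure.  All kinds include sex, total brain volume
        and acquisition-centre covariates.
    extra_covariates : tuple of str
        Additional per-scan covariate columns (e.g. head motion, global
        network strength for edge-level analyses).

    Attributes (after ``fit``)
    --------------------------
    result_ : TrajectoryFit summary.
    sm_result_ : underlying statsmodels MixedLMResults.
    """

    def __init__(self, model_kind: str = "linear", extra_covariates: tuple = ()):
        self.model_kind = model_kind
        self.extra_covariates = tuple(extra_covariates)

    def fit(self, data: pd.DataFrame, y):
        """Fit to a per-scan covariate table and response vector.

        ``data`` needs columns subject, age, sex, tbv, centre (plus any
        extra covariates); one row per scan.
        """
        y = np.asarray(y, float)
        if len(y) != len(data):
            raise ValueError("response length does not match covariate table")
        X, names, center, scales = _design(data, self.model_kind, self.extra_covariates)
        self.covariate_scales_ = scales
        groups = data["subject"].astype(str).to_numpy()
        multi = pd.Series(groups).value_counts()
        re_cols = [0, names.index("age")]
        if self.model_kind == "quadratic":
            re_cols.append(names.index("age2"))
        structure = "intercept+slope" + ("+quad" if self.model_kind == "quadratic" else "")
        if (multi >= 2).sum() < 2:
            warnings.warn(
                "fewer than 2 subjects with repeated scans: dropping random age slope",
                stacklevel=2,
            )
            re_cols = [0]
            structure = "intercept"
        res = self._fit_mixed(y, X, groups, re_cols)
        if res is None and len(re_cols) > 1:
            warnings.warn(
                "mixed model with random slope failed to converge; "
                "falling back to random intercept only",
                stacklevel=2,
            )
            re_cols = [0]
            structure = "intercept"
            res = self._fit_mixed(y, X, groups, re_cols)
        if res is None:
            raise RuntimeError("mixed model failed to converge")
        self.sm_result_ = res
        self.design_names_ = names
        self.age_center_ = center
        self.re_cols_ = re_cols
        self.groups_ = groups
        self.X_ = X
        self.result_ = self._summarize(res, names, center, structure, data, y)
        return self

    @staticmethod
    def _fit_mixed(y, X, groups, re_cols):
        """ML fit with an optimizer cascade.

        L-BFGS handles the 2x2 random structure well but often stalls on the
        3x3 quadratic structure; Powell is slower but robust there.  The
        best finite log-likelihood wins.
        """
        model = MixedLM(y, X, groups=groups, exog_re=X[:, re_cols])
        k_fe = X.shape[1]
        best = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            for method in ("lbfgs", "powell"):
                try:
                    res = model.fit(reml=False, method=method)
                except (np.linalg.LinAlgError, ValueError, OverflowError):
                    continue
                fe = np.asarray(res.params)[:k_fe]
                bse = np.asarray(res.bse)[:k_fe]
                ok = (
                    np.all(np.isfinite(fe))
                    and np.all(np.isfinite(bse))
                    and np.isfinite(res.llf)
                )
                if ok and (best is None or res.llf > best.llf + 1e-9):
                    best = res
                if ok and method == "lbfgs" and len(re_cols) < 3:
                    # the 2x2 structure is reliable under L-BFGS even when a
                    # boundary variance flags non-convergence; only the
                    # 3-component quadratic structure needs the Powell pass
                    break
        return best

    def _summarize(self, res, names, center, structure, data, y) -> TrajectoryFit:
        k_fe = len(names)
        fe = np.asarray(res.params)[:k_fe]
        cov_fe = np.asarray(res.cov_params())[:k_fe, :k_fe]
        # original-scale age slope: with centered age c, the quadratic model's
        # linear-in-age coefficient is b_age - 2*c*b_age2
        L = np.zeros(k_fe)
        L[names.index("age")] = 1.0
        if self.model_kind == "quadratic":
            L[names.index("age2")] = -2.0 * center
        beta_age = float(L @ fe)
        se = float(np.sqrt(L @ cov_fe @ L))
        t_age = beta_age / se if se > 0 else np.inf * np.sign(beta_age)
        p_age = 2 * stats.norm.sf(abs(t_age)) if np.isfinite(t_age) else 0.0
        ci = (beta_age - 1.959963984540054 * se, beta_age + 1.959963984540054 * se)
        betas = dict(zip(names, fe.tolist()))
        for name, sd in self.covariate_scales_.items():
            betas[name] = betas[name] / sd  # back to original covariate units
        cov_re = np.asarray(res.cov_re)
        rv = {"intercept": float(cov_re[0, 0])}
        if cov_re.shape[0] > 1:
            rv["age_slope"] = float(cov_re[1, 1])
        if cov_re.shape[0] > 2:
            rv["age2_slope"] = float(cov_re[2, 2])
        return TrajectoryFit(
            model_kind=self.model_kind,
            betas=betas,
            beta_age=beta_age,
            t_age=float(t_age),
            p_age=float(p_age),
            ci_age=ci,
            aic=float(res.aic),
            loglik=float(res.llf),
            random_variances=rv,
            residual_variance=float(res.scale),
            n_obs=len(y),
            n_subjects=len(np.unique(self.groups_)),
            random_structure=structure,
        )

    def bootstrap_ci_age(self, n_boot: int = 1000, seed: int | None = None,
                         level: float = 0.95) -> tuple:
        """Parametric-bootstrap percentile interval for the age slope.

        Simulates responses from the fitted model (fixed effects + subject
        random draws from the estimated covariance + residual noise) and
        refits; reproducible from ``seed``.
        """
        res = self.sm_result_
        X = self.X_
        groups = self.groups_
        re_cols = self.re_cols_
        names = self.design_names_
        k_fe = X.shape[1]
        fe = np.asarray(res.params)[:k_fe]
        cov_re = np.atleast_2d(np.asarray(res.cov_re))
        sigma = np.sqrt(res.scale)
        rng = np.random.default_rng(seed)
        uniq, inv = np.unique(groups, return_inverse=True)
        Z = X[:, re_cols]
        mean_fix = X @ fe
        # guard: a noise-free fit can leave a numerically indefinite cov_re
        evals, evecs = np.linalg.eigh(cov_re)
        chol = evecs @ np.diag(np.sqrt(np.clip(evals, 0, None)))
        est = []
        L = np.zeros(k_fe)
        L[names.index("age")] = 1.0
        if self.model_kind == "quadratic":
            L[names.index("age2")] = -2.0 * self.age_center_
        for _ in range(n_boot):
            u = rng.standard_normal((len(uniq), len(re_cols))) @ chol.T
            yb = mean_fix + np.sum(Z * u[inv], axis=1) + rng.normal(0, sigma, len(mean_fix))
            rb = self._fit_mixed(yb, X, groups, re_cols)
            if rb is None:
                rb = self._fit_mixed(yb, X, groups, [0])
            if rb is None:
                continue
            est.append(float(L @ np.asarray(rb.params)[:k_fe]))
        if not est:
            raise RuntimeError("all bootstrap refits failed")
        lo, hi = np.percentile(est, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
        return float(lo), float(hi)


def fit_lmm(y, cohort_or_data, model_kind: str = "linear",
            extra_covariates: tuple = ()) -> TrajectoryFit:
    """Fit one mixed trajectory model; accepts a Cohort or a covariate frame."""
    data = cohort_or_data.to_frame() if isinstance(cohort_or_data, Cohort) else cohort_or_data
    est = TrajectoryLMM(model_kind=model_kind, extra_covariates=extra_covariates)
    est.fit(data, y)
    return est.result_


def aic_select(fits) -> str:
    """Model kind with smallest AIC; ties resolved toward the simpler model."""
    if isinstance(fits, dict):
        items = list(fits.items())
    else:
        items = [(f.model_kind, f) for f in fits]
    return min(items, key=lambda kv: (kv[1].aic, _COMPLEXITY[kv[0]]))[0]


def ci_age(fit_estimator: TrajectoryLMM, n_boot: int = 1000,
           seed: int | None = None) -> tuple:
    return fit_estimator.bootstrap_ci_age(n_boot=n_boot, seed=seed)


def nodal_metric_matrix(cohort: Cohort, metric: str) -> np.ndarray:
    """Per-scan nodal metric values, shape (n_scans, R)."""
    from . import metrics as _m

    funcs = {
        "degree_strength": _m.degree_strength,
        "nodal_efficiency": _m.nodal_efficiency,
        "nodal_local_efficiency": _m.nodal_local_efficiency,
        "betweenness": _m.betweenness_centrality,
    }
    try:
        fn = funcs[metric]
    except KeyError:
        raise ValueError(f"unknown nodal metric '{metric}'") from None
    return np.stack([fn(s.connectome) for s in cohort.scans])


class SlopeMapper(BaseEstimator):
    """Per-region standardized developmental slopes (sklearn-style).

    For every region the nodal metric is z-scored across all scans, the
    linear mixed model is fitted, and the age-slope p-values are Bonferroni
    corrected across regions.

    Attributes (after ``fit``)
    --------------------------
    slope_map_ : SlopeMap with beta_age / t / p_bonf / significant per region.
    """

    def __init__(self, metric: str = "nodal_efficiency", alpha: float = 0.05,
                 extra_covariates: tuple = ()):
        self.metric = metric
        self.alpha = alpha
        self.extra_covariates = tuple(extra_covariates)

    def fit(self, cohort: Cohort, y=None):
        Y = y if y is not None else nodal_metric_matrix(cohort, self.metric)
        Y = np.asarray(Y, float)
        data = cohort.to_frame()
        R = Y.shape[1]
        sd = Y.std(axis=0, ddof=0)
        mu = Y.mean(axis=0)
        betas = np.zeros(R)
        ts = np.zeros(R)
        ps = np.ones(R)
        for r in range(R):
            if sd[r] == 0:
                continue
            z = (Y[:, r] - mu[r]) / sd[r]
            fit = fit_lmm(z, data, "linear", self.extra_covariates)
            betas[r] = fit.beta_age
            ts[r] = fit.t_age
            ps[r] = fit.p_age
        p_bonf = np.minimum(ps * R, 1.0)
        self.slope_map_ = SlopeMap(
            beta_age=betas, t=ts, p=ps, p_bonf=p_bonf,
            significant=p_bonf < self.alpha, metric=self.metric,
        )
        return self

    def transform(self, cohort: Cohort = None) -> np.ndarray:
        return self.slope_map_.beta_age


def fit_slope_map(cohort: Cohort, nodal_metric_name: str = "nodal_efficiency",
                  alpha: float = 0.05, y=None,
                  extra_covariates: tuple = ()) -> SlopeMap:
    mapper = SlopeMapper(metric=nodal_metric_name, alpha=alpha,
                         extra_covariates=extra_covariates)
    mapper.fit(cohort, y=y)
    return mapper.slope_map_


_AXIS_COORD = {"PA": 1, "IS": 2}


def gradient_contrast(slope_map: SlopeMap, regions: RegionTable, axis: str) -> tuple:
    """Two-group t contrast of slopes across a spatial gradient.

    Regions are split at the coordinate median along the axis: PA uses the
    y coordinate, IS the z coordinate, and ML compares lateral vs medial
    halves within each hemisphere (|x| against the per-hemisphere median).
    Returns (t, p).
    """
    beta = slope_map.beta_age
    if axis in _AXIS_COORD:
        coord = regions.centroids[:, _AXIS_COORD[axis]]
        grp_a = coord > np.median(coord)
    elif axis == "ML":
        absx = np.abs(regions.centroids[:, 0])
        grp_a = np.zeros(len(beta), dtype=bool)
        for hemi in np.unique(regions.hemisphere):
            m = regions.hemisphere == hemi
            grp_a[m] = absx[m] > np.median(absx[m])
    else:
        raise ValueError(f"unknown gradient axis '{axis}' (use PA, IS or ML)")
    a, b = beta[grp_a], beta[~grp_a]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("fewer than 3 regions in a gradient group")
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)
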