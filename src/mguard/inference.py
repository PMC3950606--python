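"""Mixed-model inference on the male-day table.

The estimation problem: does the percentage of observation time a male
spends mate-guarding (MG) on a day predict his feeding time, diet,
locomotion, restlessness or urinary C-peptide, once fruit availability
and rainfall are controlled? Each response is modelled as a Gaussian
linear mixed model with random intercepts for group and for male nested
in group, fitted by maximum likelihood (so that full and null models
are comparable by likelihood-ratio test). Continuous predictors are
z-standardized (mean 0, sample SD 1) over the model table.

Day-to-day residual dependence within a male is absorbed by a temporal
autocorrelation covariate: for each row, the Gaussian-kernel-weighted
mean of the same male's residuals from the model fitted without the
term, with the kernel width selected from a fixed grid by full-model
likelihood.

The module is organised statsmodels-style: :class:`GuardingModel` is
built from a model table (``from_dataframe``), its ``fit`` returns a
:class:`GuardingResults` carrying estimates, standard errors, the
full-vs-null LRT, VIFs and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

AC_SIGMA_GRID_DAYS = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
SMALL_CLUSTER_WARNING = (
    "random-effect variances are estimated from very few clusters "
    "(3 groups / 6 males); treat variance components as poorly identified"
)


def standardize(column: pd.Series | np.ndarray, name: str | None = None) -> np.ndarray:
    """z-standardize to mean 0, sample SD 1 (ddof=1)."""
    x = np.asarray(column, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        label = name or getattr(column, "name", None) or "column"
        raise ValueError(f"cannot standardize constant column {label!r}")
    return (x - x.mean()) / sd


def build_ac_term(
    dates: pd.Series | np.ndarray,
    male_ids: pd.Series | np.ndarray,
    residuals: np.ndarray,
    kernel_width_days: float,
) -> np.ndarray:
    """Temporal-autocorrelation covariate from same-male residuals.

    For row i the value is the weighted mean of all *other* rows of the
    same male, weights exp(-(dt days)^2 / (2 sigma^2)); weights are
    normalized, so a single neighbour contributes its residual verbatim.
    Rows with no same-male neighbour get 0.
    """
    days = np.asarray(pd.to_datetime(pd.Series(dates)).map(pd.Timestamp.toordinal), dtype=float)
    males = np.asarray(male_ids)
    resid = np.asarray(residuals, dtype=float)
    out = np.zeros(len(days))
    for male in np.unique(males):
        idx = np.flatnonzero(males == male)
        if len(idx) < 2:
            continue
        d = days[idx]
        w = np.exp(-((d[:, None] - d[None, :]) ** 2) / (2.0 * kernel_width_days**2))
        np.fill_diagonal(w, 0.0)
        totals = w.sum(axis=1)
        with np.errstate(invalid="ignore"):
            vals = (w @ resid[idx]) / totals
        vals[totals == 0] = 0.0
        out[idx] = vals
    return out


@dataclass(frozen=True)
class ModelSpec:
    """Fixed/random structure of one predefined model."""

    name: str
    response: str
    test_terms: tuple[str, ...]  # terms dropped in the null model
    controls: tuple[str, ...]
    interaction: tuple[str, str] | None = None  # fitted first, droppable
    categorical: tuple[str, ...] = ()
    use_ac_term: bool = True


_BEHAVIOUR_CONTROLS = ("fruit_index", "rainfall_mm")
_UCP_MG_CONTROLS = (
    "fruit_index",
    "rainfall_mm",
    "collection_time",
    "storage_months",
    "hourly_vertical_m",
    "pct_feeding",
)

#: the predefined model battery: five daily behavioural responses tested
#: against MG time, the UCP/MG model, and the UCP/rank model
MODEL_SPECS: dict[str, ModelSpec] = {
    spec.name: spec
    for spec in [
        ModelSpec("feeding", "pct_feeding", ("mg_pct",), _BEHAVIOUR_CONTROLS, ("mg_pct", "fruit_index")),
        ModelSpec("fruit_diet", "pct_fruit_in_diet", ("mg_pct",), _BEHAVIOUR_CONTROLS, ("mg_pct", "fruit_index")),
        ModelSpec("distance", "hourly_distance_m", ("mg_pct",), _BEHAVIOUR_CONTROLS, ("mg_pct", "fruit_index")),
        ModelSpec("vertical", "hourly_vertical_m", ("mg_pct",), _BEHAVIOUR_CONTROLS, ("mg_pct", "fruit_index")),
        ModelSpec("restlessness", "restlessness", ("mg_pct",), _BEHAVIOUR_CONTROLS, ("mg_pct", "fruit_index")),
        ModelSpec("ucp_mg", "ucp_ng_per_mg_creatinine", ("mg_pct",), _UCP_MG_CONTROLS, None, use_ac_term=False),
        ModelSpec(
            "ucp_rank",
            "ucp_ng_per_mg_creatinine",
            ("rank_class",),
            ("fruit_index", "collection_time", "storage_months"),
            None,
            categorical=("rank_class",),
            use_ac_term=False,
        ),
    ]
}


@dataclass
class LRTResult:
    chi2: float
    df: int
    pvalue: float


def lrt(full, null) -> LRTResult:
    """Full-vs-null likelihood-ratio test (both fitted by ML on the same data).

    Accepts statsmodels results or :class:`GuardingResults`; chi-square
    is clipped at 0 (boundary fits can give tiny negative 2*dllf).
    """

    def _llf_k(res):
        if isinstance(res, GuardingResults):
            return res.llf, len(res.fe_params)
        return res.llf, res.model.k_fe if hasattr(res.model, "k_fe") else res.df_model + 1

    llf_full, k_full = _llf_k(full)
    llf_null, k_null = _llf_k(null)
    df = k_full - k_null
    if df < 0:
        raise ValueError("null model has more fixed-effect parameters than the full model")
    chi2 = max(0.0, 2.0 * (llf_full - llf_null))
    p = 1.0 if df == 0 else float(scipy.stats.chi2.sf(chi2, df))
    return LRTResult(chi2, df, p)


def vif(table: pd.DataFrame, predictors: list[str]) -> pd.Series:
    """Variance inflation factor per predictor: 1 / (1 - R^2) of the
    regression of that predictor on all the others (plus intercept).
    Perfect collinearity reports inf."""
    if len(predictors) < 2:
        raise ValueError("VIF needs at least 2 predictors")
    X = table[predictors].astype(float).to_numpy()
    out = {}
    for j, name in enumerate(predictors):
        y = X[:, j]
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        sst = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / sst if sst > 0 else 1.0
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def _term_label(term: str, categorical: tuple[str, ...]) -> str:
    return f"C({term})" if term in categorical else term


def _fit_mixedlm(table: pd.DataFrame, response: str, fixed: list[str]):
    """One ML MixedLM fit: random intercepts for group and male-in-group."""
    rhs = " + ".join(fixed) if fixed else "1"
    model = smf.mixedlm(
        f"{response} ~ {rhs}",
        table,
        groups="group_id",
        re_formula="1",
        vc_formula={"male": "0 + C(male_id)"},
    )
    # Powell reaches the ML optimum far more reliably than L-BFGS on
    # these small-cluster likelihoods (gradient methods stall early and
    # corrupt full-vs-null likelihood differences); fall back if needed.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = model.fit(reml=False, method="powell")
        except (np.linalg.LinAlgError, ValueError):
            res = None
        if res is None or not res.converged:
            alt = model.fit(reml=False, method="lbfgs")
            if res is None or alt.llf > res.llf:
                res = alt
    return res


class GuardingModel:
    """Linear mixed model of one daily response on mate-guarding time.

    Parameters
    ----------
    table
        Male-day (or per-sample) model table with the spec's columns plus
        ``male_id``, ``group_id`` and ``date``. Rows with missing values
        in the used columns are dropped (with the count recorded).
    spec
        A :class:`ModelSpec`, or the name of a predefined one.
    standardize_predictors
        z-standardize continuous predictors over the table (default).
    ac_sigma_grid
        Kernel widths (days) searched for the autocorrelation term; a
        single value pins the width without a search.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        spec: ModelSpec | str,
        standardize_predictors: bool = True,
        ac_sigma_grid: tuple[float, ...] = AC_SIGMA_GRID_DAYS,
    ):
        self.spec = MODEL_SPECS[spec] if isinstance(spec, str) else spec
        self.ac_sigma_grid = tuple(ac_sigma_grid)
        terms = list(self.spec.test_terms) + list(self.spec.controls)
        needed = [self.spec.response, *terms, "male_id", "group_id", "date"]
        data = table[needed].dropna().reset_index(drop=True).copy()
        self.n_dropped = len(table) - len(data)
        if standardize_predictors:
            for t in terms:
                if t not in self.spec.categorical:
                    data[t] = standardize(data[t], t)
        if self.spec.interaction is not None:
            a, b = self.spec.interaction
            data["interaction"] = data[a] * data[b]
        self.table = data

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, spec: ModelSpec | str, **kwargs) -> "GuardingModel":
        return cls(table, spec, **kwargs)

    def _fixed_terms(self, with_test: bool, with_interaction: bool) -> list[str]:
        cat = self.spec.categorical
        terms = [_term_label(t, cat) for t in self.spec.controls]
        if with_test:
            terms = [_term_label(t, cat) for t in self.spec.test_terms] + terms
        if with_interaction and self.spec.interaction is not None:
            terms.append("interaction")
        return terms

    def fit(self, include_interaction: bool = False, ac_sigma: float | None = None) -> "GuardingResults":
        """ML fit of the full model; returns results with the full-vs-null LRT.

        The MG x fruit interaction is excluded by default (it is fitted
        and gated separately by :meth:`interaction_pvalue`); the null
        model drops the test term(s) but keeps every control and the
        autocorrelation covariate.
        """
        warnings.warn(SMALL_CLUSTER_WARNING, UserWarning, stacklevel=2)
        data = self.table.copy()
        fixed_full = self._fixed_terms(with_test=True, with_interaction=include_interaction)
        fixed_null = self._fixed_terms(with_test=False, with_interaction=False)

        sigma = ac_sigma
        if self.spec.use_ac_term:
            # residuals come from the null-structure model fitted without
            # the AC term; the same AC column then enters full and null
            base = _fit_mixedlm(data, self.spec.response, fixed_null)
            resid = np.asarray(base.resid)
            if sigma is None:
                best = None
                for s in self.ac_sigma_grid:
                    data["ac_term"] = build_ac_term(data["date"], data["male_id"], resid, s)
                    cand = _fit_mixedlm(data, self.spec.response, fixed_full + ["ac_term"])
                    if best is None or cand.llf > best[1].llf:
                        best = (s, cand)
                sigma, full = best
                data["ac_term"] = build_ac_term(data["date"], data["male_id"], resid, sigma)
            else:
                data["ac_term"] = build_ac_term(data["date"], data["male_id"], resid, sigma)
                full = _fit_mixedlm(data, self.spec.response, fixed_full + ["ac_term"])
            null = _fit_mixedlm(data, self.spec.response, fixed_null + ["ac_term"])
        else:
            full = _fit_mixedlm(data, self.spec.response, fixed_full)
            null = _fit_mixedlm(data, self.spec.response, fixed_null)
            sigma = None

        test = lrt(full, null)
        vif_cols = [t for t in (list(self.spec.test_terms) + list(self.spec.controls)) if t not in self.spec.categorical]
        if self.spec.categorical:
            # dichotomous factors enter the VIF regression as 0/1
            for t in self.spec.categorical:
                data[f"_{t}_num"] = pd.factorize(data[t])[0].astype(float)
                vif_cols.append(f"_{t}_num")
        vifs = vif(data, vif_cols) if len(vif_cols) >= 2 else pd.Series(dtype=float)
        vifs.index = [i.strip("_").removesuffix("_num") for i in vifs.index]
        return GuardingResults(
            model=self,
            result=full,
            null_result=null,
            lrt_full_null=test,
            ac_sigma_days=sigma,
            vifs=vifs,
            n_obs=len(data),
            converged=bool(full.converged and null.converged),
        )

    def interaction_pvalue(self) -> float:
        """LRT p of the MG x fruit interaction (full-with vs full-without);
        the reporting path drops the interaction when this exceeds 0.05."""
        if self.spec.interaction is None:
            raise ValueError(f"model {self.spec.name!r} has no interaction term")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            with_int = self.fit(include_interaction=True)
            without = self.fit(include_interaction=False)
        return lrt(with_int, without).pvalue


@dataclass
class GuardingResults:
    """Fitted mixed model: estimates, uncertainties and diagnostics."""

    model: GuardingModel
    result: object  # statsmodels MixedLMResults (full model)
    null_result: object
    lrt_full_null: LRTResult
    ac_sigma_days: float | None
    vifs: pd.Series
    n_obs: int
    converged: bool
    warnings_: list = field(default_factory=list)

    @property
    def fe_params(self) -> pd.Series:
        return self.result.fe_params

    @property
    def bse(self) -> pd.Series:
        return self.result.bse_fe

    @property
    def llf(self) -> float:
        return float(self.result.llf)

    @property
    def random_effect_variances(self) -> pd.Series:
        out = {"group": float(self.result.cov_re.iloc[0, 0])}
        for name, v in zip(self.result.model.exog_vc.names, np.atleast_1d(self.result.vcomp)):
            out[name] = float(v)
        out["residual"] = float(self.result.scale)
        return pd.Series(out)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = scipy.stats.norm.ppf(1 - alpha / 2)
        lo = self.fe_params - z * self.bse
        hi = self.fe_params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            f"Mixed model: {spec.response} ~ {' + '.join(spec.test_terms + spec.controls)}",
            f"  random intercepts: group, male-in-group; ML; n = {self.n_obs}"
            + ("" if self.converged else "  [NOT CONVERGED]"),
        ]
        if self.ac_sigma_days is not None:
            lines.append(f"  autocorrelation term: Gaussian kernel, sigma = {self.ac_sigma_days} d")
        lines.append(
            f"  full vs null LRT: chi2 = {self.lrt_full_null.chi2:.2f}, "
            f"df = {self.lrt_full_null.df}, p = {self.lrt_full_null.pvalue:.4g}"
        )
        lines.append("  fixed effects (estimate +/- SE):")
        for name in self.fe_params.index:
            lines.append(f"    {name:<28s} {self.fe_params[name]: .3f} +/- {self.bse[name]:.3f}")
        if len(self.vifs):
            lines.append("  VIF: " + ", ".join(f"{k}={v:.2f}" for k, v in self.vifs.items()))
            if (self.vifs >= 5).any():
                lines.append("  WARNING: VIF >= 5, predictors strongly collinear")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model.spec.name,
            "response": self.model.spec.response,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "estimates": {k: float(v) for k, v in self.fe_params.items()},
            "se": {k: float(v) for k, v in self.bse.items()},
            "llf": self.llf,
            "ac_sigma_days": self.ac_sigma_days,
            "lrt": {
                "chi2": self.lrt_full_null.chi2,
                "df": self.lrt_full_null.df,
                "p": self.lrt_full_null.pvalue,
            },
            "vif": {k: float(v) for k, v in self.vifs.items()},
        }


def fit_model(table: pd.DataFrame, spec: ModelSpec | str, **kwargs) -> GuardingResults:
    """Convenience wrapper: build a :class:`GuardingModel` and fit it."""
    fit_kwargs = {k: kwargs.pop(k) for k in ("include_interaction", "ac_sigma") if k in kwargs}
    return GuardingModel(table, spec, **kwargs).fit(**fit_kwargs)
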