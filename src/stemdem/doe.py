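"""Design-of-experiments calibration statistics.

The bond parameters of the stem model are calibrated against the measured
peak compression force in three stages: a two-level Plackett–Burman screen
over all eleven contact and bond factors, a steepest-ascent march that
narrows the significant factors' ranges, and a face-centred central
composite design (CCD) whose responses support a full second-order response
surface.  The fitted surface is then inverted to the target force by
bounded optimisation.

The response surface is exposed statsmodels-style: build a
:class:`ResponseSurface` from a :class:`DesignMatrix`, call ``fit()`` and
work with the returned :class:`ResponseSurfaceResults` (coefficients,
ANOVA, ``summary()``).  Thin functional wrappers (``fit_quadratic``,
``anova``) cover the same ground for script use.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import minimize

__all__ = [
    "FactorDef",
    "DesignMatrix",
    "AscentPath",
    "TargetOptimization",
    "QuadraticModel",
    "ResponseSurface",
    "ResponseSurfaceResults",
    "generate_pb_design",
    "pb_effects",
    "ascent_step",
    "generate_ccd",
    "fit_quadratic",
    "anova",
    "optimize_to_target",
    "PB_FACTORS",
    "CCD_FACTORS",
]


@dataclass(frozen=True)
class FactorDef:
    """One design factor with its physical range and role."""

    name: str
    low: float
    high: float
    role: str = "bond"  # "contact" or "bond"

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"factor {self.name}: low must be below high")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def half_range(self) -> float:
        return 0.5 * (self.high - self.low)

    def decode(self, coded):
        """Coded [-1, 1] -> physical units."""
        return self.center + np.asarray(coded) * self.half_range

    def encode(self, physical):
        """Physical units -> coded."""
        return (np.asarray(physical) - self.center) / self.half_range


#: the eleven screening factors: six measured contact coefficients (mid-range
#: bounds from the tilt/drop tests) and five bond parameters.
PB_FACTORS = [
    FactorDef("A", 0.37, 0.60, "contact"),  # particle-particle restitution
    FactorDef("B", 0.45, 0.57, "contact"),  # particle-particle static friction
    FactorDef("C", 0.22, 0.30, "contact"),  # particle-particle rolling friction
    FactorDef("D", 0.44, 0.64, "contact"),  # particle-tool restitution
    FactorDef("E", 0.42, 0.51, "contact"),  # particle-tool static friction
    FactorDef("F", 0.12, 0.21, "contact"),  # particle-tool rolling friction
    FactorDef("K_n", 1e9, 1e11),
    FactorDef("K_s", 1e9, 1e11),
    FactorDef("sigma_m", 1e7, 1e10),
    FactorDef("tau_m", 1e7, 1e10),
    FactorDef("R_ab", 0.6, 1.0),
]

#: CCD factors after screening and steepest ascent.
CCD_FACTORS = [
    FactorDef("K_n", 1e10, 5e10),
    FactorDef("K_s", 1e10, 5e10),
    FactorDef("tau_m", 1e8, 1e10),
    FactorDef("R_ab", 0.6, 1.0),
]

#: critical normal stress held fixed (mid-range of its screening interval)
SIGMA_M_FIXED = 5.005e9


@dataclass
class DesignMatrix:
    """Coded design runs plus (optionally) their responses.

    ``runs`` holds coded levels in {-1, 0, +1}; repeated responses per run
    (a 2-D array) are averaged on assignment.
    """

    factors: list[FactorDef]
    runs: np.ndarray
    responses: np.ndarray | None = None

    def __post_init__(self):
        self.runs = np.asarray(self.runs, float)
        if self.runs.ndim != 2 or self.runs.shape[1] != len(self.factors):
            raise ValueError("runs must be (n_runs, n_factors)")
        if self.responses is not None:
            y = np.asarray(self.responses, float)
            if y.ndim == 2:
                y = y.mean(axis=1)
            if len(y) != len(self.runs):
                raise ValueError("response count must equal run count")
            self.responses = y

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.factors]

    def with_responses(self, responses) -> "DesignMatrix":
        return DesignMatrix(self.factors, self.runs.copy(), responses)

    def to_physical(self) -> pd.DataFrame:
        cols = {
            f.name: f.decode(self.runs[:, j]) for j, f in enumerate(self.factors)
        }
        df = pd.DataFrame(cols)
        if self.responses is not None:
            df["response"] = self.responses
        return df

    def to_coded_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.runs, columns=self.names)
        if self.responses is not None:
            df["response"] = self.responses
        return df


# --------------------------------------------------------------------- PB

# First row of the cyclic 20-run Plackett-Burman array.
_PB20_GENERATOR = np.array(
    [1, 1, -1, -1, 1, 1, 1, 1, -1, 1, -1, 1, -1, -1, -1, -1, 1, 1, -1]
)


def generate_pb_design(
    factors: list[FactorDef] | None = None, center_points: int = 1
) -> DesignMatrix:
    """20-run Plackett–Burman screening design plus centre points.

    Columns are cyclic shifts of the 19-element generator row closed by an
    all-minus run; every column is balanced (ten +1, ten -1) and any two
    columns are orthogonal.  Up to eleven factors are supported here (the
    screening slate); remaining columns are dropped.
    """
    if factors is None:
        factors = PB_FACTORS
    k = len(factors)
    if not 1 <= k <= 19:
        raise ValueError("the 20-run Plackett-Burman array supports 1-19 factors")
    rows = np.array([np.roll(_PB20_GENERATOR, i) for i in range(19)])
    rows = np.vstack([rows, -np.ones(19)])
    runs = rows[:, :k]
    if center_points:
        runs = np.vstack([runs, np.zeros((center_points, k))])
    return DesignMatrix(list(factors), runs)


def pb_effects(design: DesignMatrix) -> pd.DataFrame:
    """Main effects from a two-level screening design, Pareto-ordered.

    The effect of a factor is the mean response at its high level minus the
    mean at its low level (centre points excluded); standardisation uses the
    t statistic of the equivalent first-order regression.  Returns a frame
    sorted by decreasing |t|.
    """
    if design.responses is None:
        raise ValueError("design has no responses")
    two_level = np.abs(design.runs).sum(axis=1) > 0
    X = design.runs[two_level]
    y = design.responses[two_level]
    effects = np.array(
        [y[X[:, j] > 0].mean() - y[X[:, j] < 0].mean() for j in range(X.shape[1])]
    )
    ols = sm.OLS(y, sm.add_constant(X)).fit()
    out = pd.DataFrame(
        {
            "factor": design.names,
            "effect": effects,
            "t": ols.tvalues[1:],
            "p": ols.pvalues[1:],
        }
    )
    return out.reindex(out["t"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )


# ------------------------------------------------------------------ ascent


@dataclass
class AscentPath:
    """Steepest-ascent runs: physical factor settings, responses and the
    relative error of each run against the laboratory mean."""

    runs: pd.DataFrame
    responses: np.ndarray
    delta_e: np.ndarray | None = None

    @property
    def best_run(self) -> int:
        if self.delta_e is None:
            raise ValueError("call ascent_step first")
        return int(np.argmin(self.delta_e))


def ascent_step(path: AscentPath, f_ave: float) -> AscentPath:
    """Attach the relative error ``100 |F_max - F_ave| / F_ave`` per run."""
    if f_ave <= 0:
        raise ValueError("reference force must be positive")
    de = 100.0 * np.abs(np.asarray(path.responses) - f_ave) / f_ave
    return AscentPath(runs=path.runs, responses=path.responses, delta_e=de)


# --------------------------------------------------------------------- CCD


def generate_ccd(
    factors: list[FactorDef] | None = None, center_points: int = 3
) -> DesignMatrix:
    """Face-centred central composite design.

    For k factors: 2^k factorial corners, 2k axial runs at ±1 on a single
    factor (face-centred, axial distance 1, hence a three-level design) and
    the given number of centre replicates.  k=4 with 3 centres gives the
    27-run layout used for the bond calibration.
    """
    if factors is None:
        factors = CCD_FACTORS
    k = len(factors)
    corners = np.array(list(itertools.product((-1.0, 1.0), repeat=k)))
    axial = np.zeros((2 * k, k))
    for j in range(k):
        axial[2 * j, j] = -1.0
        axial[2 * j + 1, j] = 1.0
    center = np.zeros((center_points, k))
    return DesignMatrix(list(factors), np.vstack([corners, axial, center]))


# ------------------------------------------------------- response surface


def _term_names(names: list[str]) -> list[str]:
    inter = [f"{a}:{b}" for a, b in itertools.combinations(names, 2)]
    quad = [f"{n}^2" for n in names]
    return ["intercept"] + list(names) + inter + quad


def _expand_quadratic(X: np.ndarray) -> np.ndarray:
    """Full second-order model matrix in coded units."""
    n, k = X.shape
    cols = [np.ones(n)] + [X[:, j] for j in range(k)]
    for i, j in itertools.combinations(range(k), 2):
        cols.append(X[:, i] * X[:, j])
    for j in range(k):
        cols.append(X[:, j] ** 2)
    return np.column_stack(cols)


@dataclass(frozen=True)
class QuadraticModel:
    """Second-order response surface in coded units."""

    factors: tuple[FactorDef, ...]
    coef: np.ndarray  # ordered as _term_names

    @property
    def term_names(self) -> list[str]:
        return _term_names([f.name for f in self.factors])

    @property
    def intercept(self) -> float:
        return float(self.coef[0])

    def coefficients(self) -> pd.Series:
        return pd.Series(self.coef, index=self.term_names)

    def predict_coded(self, x) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        return _expand_quadratic(x) @ self.coef

    def predict_physical(self, x_phys) -> np.ndarray:
        x_phys = np.atleast_2d(np.asarray(x_phys, float))
        coded = np.column_stack(
            [f.encode(x_phys[:, j]) for j, f in enumerate(self.factors)]
        )
        return self.predict_coded(coded)


class ResponseSurface:
    """Second-order response-surface model of a coded design (OLS)."""

    def __init__(self, design: DesignMatrix):
        if design.responses is None:
            raise ValueError("design must carry responses")
        k = design.runs.shape[1]
        n_terms = 1 + k + k * (k - 1) // 2 + k
        if design.n_runs < n_terms:
            raise ValueError(
                f"{design.n_runs} runs cannot identify {n_terms} quadratic terms"
            )
        self.design = design
        self.exog = _expand_quadratic(design.runs)
        if np.linalg.matrix_rank(self.exog) < n_terms:
            raise ValueError("design is rank deficient for the quadratic model")
        self.endog = design.responses

    def fit(self) -> "ResponseSurfaceResults":
        res = sm.OLS(self.endog, self.exog).fit()
        return ResponseSurfaceResults(self, res)


class ResponseSurfaceResults:
    """Fitted response surface: coefficients, fit statistics and ANOVA."""

    def __init__(self, model: ResponseSurface, ols_results):
        self.model = model
        self._ols = ols_results
        self.quadratic = QuadraticModel(
            factors=tuple(model.design.factors), coef=np.asarray(ols_results.params)
        )

    # -- convenience passthroughs -------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(np.asarray(self._ols.params), index=self.quadratic.term_names)

    @property
    def rsquared(self) -> float:
        return float(self._ols.rsquared)

    @property
    def rsquared_adj(self) -> float:
        return float(self._ols.rsquared_adj)

    @property
    def fvalue(self) -> float:
        return float(self._ols.fvalue)

    @property
    def df_resid(self) -> int:
        return int(self._ols.df_resid)

    @property
    def cv_percent(self) -> float:
        """Coefficient of variation: 100 sqrt(MS_resid) / mean response."""
        return 100.0 * np.sqrt(self._ols.mse_resid) / self.model.endog.mean()

    def predict_coded(self, x) -> np.ndarray:
        return self.quadratic.predict_coded(x)

    def predict_physical(self, x) -> np.ndarray:
        return self.quadratic.predict_physical(x)

    # -- ANOVA ----------------------------------------------------------
    def anova(self) -> pd.DataFrame:
        """Partial (Type III) ANOVA in coded units.

        Per-term sums of squares are the partial SS of each single-df term;
        lack of fit is separated from pure error using replicated runs
        (identical coded rows).  Stars mark p<0.05 (*) and p<0.01 (**).
        """
        ols = self._ols
        y = self.model.endog
        names = self.quadratic.term_names[1:]
        ms_res = ols.mse_resid
        ss_res = float(ols.ssr)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        ss_model = ss_tot - ss_res
        df_model = int(ols.df_model)
        rows = []
        f_model = (ss_model / df_model) / ms_res
        p_model = stats.f.sf(f_model, df_model, ols.df_resid)
        rows.append(("Model", ss_model, df_model, ss_model / df_model, f_model, p_model))
        # single-df partial SS equals t^2 * MS_res
        for name, t in zip(names, np.asarray(ols.tvalues)[1:]):
            ss = float(t * t * ms_res)
            p = stats.f.sf(t * t, 1, ols.df_resid)
            rows.append((name, ss, 1, ss, float(t * t), float(p)))
        # pure error from replicate groups
        runs = self.model.design.runs
        _, inverse = np.unique(runs, axis=0, return_inverse=True)
        ss_pe, df_pe = 0.0, 0
        for g in np.unique(inverse):
            yg = y[inverse == g]
            if len(yg) > 1:
                ss_pe += float(((yg - yg.mean()) ** 2).sum())
                df_pe += len(yg) - 1
        df_lof = int(ols.df_resid) - df_pe
        rows.append(("Residual", ss_res, int(ols.df_resid), ms_res, np.nan, np.nan))
        if df_pe > 0 and df_lof > 0:
            ss_lof = ss_res - ss_pe
            f_lof = (ss_lof / df_lof) / (ss_pe / df_pe)
            p_lof = stats.f.sf(f_lof, df_lof, df_pe)
            rows.append(("Lack of Fit", ss_lof, df_lof, ss_lof / df_lof, f_lof, p_lof))
            rows.append(("Pure Error", ss_pe, df_pe, ss_pe / df_pe, np.nan, np.nan))
        else:
            rows.append(("Lack of Fit", np.nan, df_lof, np.nan, np.nan, np.nan))
        rows.append(("Cor Total", ss_tot, len(y) - 1, np.nan, np.nan, np.nan))
        df = pd.DataFrame(
            rows, columns=["source", "sum_sq", "df", "mean_sq", "F", "p"]
        )
        df["sig"] = [
            "**" if p < 0.01 else "*" if p < 0.05 else ""
            for p in df["p"].fillna(1.0)
        ]
        return df

    def summary(self) -> str:
        lines = [
            "Second-order response surface (coded units)",
            "=" * 46,
            self.params.round(2).to_string(),
            "-" * 46,
            f"R^2 = {self.rsquared:.4f}   adj R^2 = {self.rsquared_adj:.4f}",
            f"model F = {self.fvalue:.2f} on ({int(self._ols.df_model)}, "
            f"{self.df_resid}) df   CV = {self.cv_percent:.2f}%",
        ]
        return "\n".join(lines)


def fit_quadratic(design: DesignMatrix) -> ResponseSurfaceResults:
    """OLS fit of the full second-order model in coded units."""
    return ResponseSurface(design).fit()


def anova(results: ResponseSurfaceResults) -> pd.DataFrame:
    """ANOVA table of a fitted response surface."""
    return results.anova()


# ------------------------------------------------------------ optimisation


@dataclass
class TargetOptimization:
    """Constrained inversion: find factor settings whose predicted response
    hits ``target_force`` within box ``bounds`` (physical units)."""

    target_force: float
    bounds: dict[str, tuple[float, float]]
    n_starts: int = 32
    seed: int = 0
    tolerance: float = 0.1  # N

    solution: dict[str, float] | None = None
    predicted: float | None = None
    converged: bool | None = None


def optimize_to_target(
    model: QuadraticModel | ResponseSurfaceResults, problem: TargetOptimization
) -> TargetOptimization:
    """Multi-start bounded minimisation of ``(prediction - target)^2``.

    Starts are drawn deterministically from ``problem.seed``.  The best
    solution is reported in physical units together with the predicted
    force; ``converged`` is False when no start reaches the tolerance.
    """
    if isinstance(model, ResponseSurfaceResults):
        model = model.quadratic
    factors = model.factors
    lo = np.array([problem.bounds[f.name][0] for f in factors])
    hi = np.array([problem.bounds[f.name][1] for f in factors])
    if np.any(lo >= hi):
        raise ValueError("invalid bounds: low must be below high")
    lo_c = np.array([f.encode(v) for f, v in zip(factors, lo)])
    hi_c = np.array([f.encode(v) for f, v in zip(factors, hi)])

    def objective(xc):
        return float((model.predict_coded(xc)[0] - problem.target_force) ** 2)

    rng = np.random.default_rng(problem.seed)
    starts = lo_c + (hi_c - lo_c) * rng.random((problem.n_starts, len(factors)))
    best = None
    for x0 in starts:
        res = minimize(
            objective, x0, method="L-BFGS-B", bounds=list(zip(lo_c, hi_c))
        )
        if best is None or res.fun < best.fun:
            best = res
    xc = np.clip(best.x, lo_c, hi_c)
    phys = {f.name: float(f.decode(v)) for f, v in zip(factors, xc)}
    pred = float(model.predict_coded(xc)[0])
    problem.solution = phys
    problem.predicted = pred
    problem.converged = abs(pred - problem.target_force) <= problem.tolerance
    return problem
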