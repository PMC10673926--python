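"""Random-intercept linear mixed models by profiled REML, and everything
built on top of them: repeatability (intraclass correlation), parametric
simulation confidence intervals, likelihood-ratio p-values, stepwise-backward
model selection, and partial / marginal / conditional R².

Model
-----
For observation ``j`` of individual ``i``::

    y_ij = x_ij' beta + u_i + e_ij,   u_i ~ N(0, V_ID),   e_ij ~ N(0, V_res)

With a single random intercept the covariance of ``y`` is
``V_res * (I + lambda * Z Z')`` where ``lambda = V_ID / V_res``.  For fixed
``lambda`` the GLS estimate of ``beta`` and the profiled error variance are
available in closed form (block-diagonal structure, one rank-one update per
group), so (RE)ML fitting reduces to a one-dimensional optimisation over
``log(lambda)``.  Repeatability is ``R = V_ID / (V_ID + V_res)``.

The restricted log-likelihood used throughout (and in the brute-force grid
oracle in the test suite) is, with ``V* = I + lambda Z Z'``,
``A = X' V*^{-1} X``, ``q = r' V*^{-1} r`` the GLS residual quadratic form and
``sigma^2 = q / (n - p)``::

    l_R = -1/2 [ (n-p)(log sigma^2 + 1 + log 2pi) + log|V*| + log|A| ]

and the ML log-likelihood (used for fixed-effect likelihood-ratio tests)
replaces ``n - p`` by ``n`` and drops the ``log|A|`` term.

Plain linear models are the ``random_group=None`` special case: ordinary
least squares with partial F-tests for term p-values.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .errors import (
    CIUnreliableError,
    ConvergenceError,
    InsufficientDataError,
    RankError,
    ValidationError,
)

_LOG2PI = math.log(2.0 * math.pi)

# lambda = V_ID/V_res is profiled on the log scale within these bounds;
# hitting the lower bound is reported as V_ID = 0 (REML boundary convention).
_LOG_LAMBDA_BOUNDS = (-16.0, 16.0)


# ---------------------------------------------------------------------------
# Model specification and formula grammar
# ---------------------------------------------------------------------------

_RANDOM_RE = re.compile(r"\(\s*1\s*\|\s*([A-Za-z_]\w*)\s*\)")
_LOG_RE = re.compile(r"^log\(\s*([A-Za-z_]\w*)\s*\)$")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description.

    ``fixed_terms`` are column names, optionally containing interaction terms
    written ``a:b``.  ``random_group`` names the grouping column for the
    random intercept (``None`` gives a plain linear model).  When
    ``log_response`` is set the response column is log-transformed before
    fitting (used for activity, which is log-transformed for normality).
    """

    response: str
    fixed_terms: tuple[str, ...] = ()
    random_group: str | None = None
    log_response: bool = False

    def __post_init__(self):
        terms = tuple(self.fixed_terms)
        object.__setattr__(self, "fixed_terms", terms)
        if len(set(terms)) != len(terms):
            raise ValidationError(f"duplicated fixed terms in {terms}")

    def without(self, term: str) -> "ModelSpec":
        if term not in self.fixed_terms:
            raise KeyError(f"term {term!r} not in model")
        return replace(
            self, fixed_terms=tuple(t for t in self.fixed_terms if t != term)
        )

    @property
    def formula(self) -> str:
        lhs = f"log({self.response})" if self.log_response else self.response
        rhs = " + ".join(self.fixed_terms) if self.fixed_terms else "1"
        if self.random_group:
            rhs += f" + (1|{self.random_group})"
        return f"{lhs} ~ {rhs}"


def parse_formula(formula: str) -> ModelSpec:
    """Parse the minimal ``response ~ a + b + a:b + (1|id)`` grammar."""
    if formula.count("~") != 1:
        raise ValidationError(f"formula must contain exactly one '~': {formula!r}")
    lhs, rhs = (s.strip() for s in formula.split("~"))
    log_response = False
    m = _LOG_RE.match(lhs)
    if m:
        log_response = True
        lhs = m.group(1)
    if not lhs:
        raise ValidationError("empty response in formula")
    random_group = None
    fixed: list[str] = []
    for raw in rhs.split("+"):
        tok = raw.strip()
        if not tok or tok == "1":
            continue
        m = _RANDOM_RE.fullmatch(tok)
        if m:
            if random_group is not None:
                raise ValidationError("only one random intercept term is supported")
            random_group = m.group(1)
        else:
            fixed.append(tok)
    return ModelSpec(lhs, tuple(fixed), random_group, log_response)


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def _is_categorical(s: pd.Series) -> bool:
    return (
        isinstance(s.dtype, pd.CategoricalDtype)
        or s.dtype == object
        or pd.api.types.is_bool_dtype(s)
        or pd.api.types.is_string_dtype(s)
    )


def _base_columns(df: pd.DataFrame, name: str) -> tuple[np.ndarray, list[str]]:
    """Columns for a single (non-interaction) term; treatment coding."""
    if name not in df.columns:
        raise ValidationError(f"column {name!r} not found in data")
    s = df[name]
    if _is_categorical(s):
        levels = sorted(pd.unique(s.dropna()).tolist(), key=str)
        cols = np.column_stack(
            [(s.to_numpy() == lev).astype(float) for lev in levels[1:]]
        ) if len(levels) > 1 else np.empty((len(df), 0))
        names = [f"{name}[{lev}]" for lev in levels[1:]]
        return cols, names
    return s.to_numpy(dtype=float)[:, None], [name]


def _term_columns(df: pd.DataFrame, term: str) -> tuple[np.ndarray, list[str]]:
    parts = [p.strip() for p in term.split(":")]
    mat, names = _base_columns(df, parts[0])
    for part in parts[1:]:
        m2, n2 = _base_columns(df, part)
        mat = np.einsum("ij,ik->ijk", mat, m2).reshape(len(df), -1)
        names = [f"{a}:{b}" for a in names for b in n2]
    return mat, names


def build_design(
    df: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str], dict[str, list[int]]]:
    """Design matrix, response, column names, term -> column indices, and the
    complete-case frame for ``spec``.

    The first column of X is the intercept.  The response is log-transformed
    when the spec requests it.
    """
    used = [spec.response]
    for t in spec.fixed_terms:
        used.extend(p.strip() for p in t.split(":"))
    if spec.random_group:
        used.append(spec.random_group)
    for c in dict.fromkeys(used):
        if c not in df.columns:
            raise ValidationError(f"column {c!r} not found in data")
    df = df.dropna(subset=list(dict.fromkeys(used)))
    if df.empty:
        raise InsufficientDataError("no complete-case rows")

    blocks = [np.ones((len(df), 1))]
    names = ["(Intercept)"]
    term_cols: dict[str, list[int]] = {}
    pos = 1
    for term in spec.fixed_terms:
        mat, tnames = _term_columns(df, term)
        blocks.append(mat)
        names.extend(tnames)
        term_cols[term] = list(range(pos, pos + mat.shape[1]))
        pos += mat.shape[1]
    X = np.hstack(blocks)
    y = df[spec.response].to_numpy(dtype=float)
    if spec.log_response:
        if np.any(y <= 0):
            raise ValidationError(
                f"log transform of {spec.response!r} requires positive values"
            )
        y = np.log(y)
    return X, y, names, term_cols, df


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        bad = sorted(names[j] for j in piv[rank:])
        raise RankError(f"singular fixed-effects design; collinear columns: {bad}")


# ---------------------------------------------------------------------------
# Profiled (RE)ML engine
# ---------------------------------------------------------------------------

class _GroupedDesign:
    """Design sorted by group, with cached sufficient statistics.

    Each (RE)ML evaluation at a given lambda needs only the per-group sums of
    rows of X and of y plus the crossproducts X'X, X'y, y'y, so a full
    1-D profile fit costs O(n p) once plus O(q p^2) per likelihood call.
    Reused across the hundreds of refits in parametric simulation CIs.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, codes: np.ndarray):
        order = np.argsort(codes, kind="stable")
        self.order = order
        self.X = np.ascontiguousarray(X[order])
        self.codes = codes[order]
        self.n, self.p = X.shape
        self.starts = np.flatnonzero(
            np.r_[True, self.codes[1:] != self.codes[:-1]]
        )
        self.ni = np.diff(np.r_[self.starts, self.n]).astype(float)
        self.q = len(self.ni)
        self.Sx = np.add.reduceat(self.X, self.starts, axis=0)
        self.XtX = self.X.T @ self.X
        self.set_y(y[order], presorted=True)

    def set_y(self, y: np.ndarray, presorted: bool = False) -> None:
        self.y = y if presorted else y[self.order]
        self.sy = np.add.reduceat(self.y, self.starts)
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)

    def _components(self, lam: float):
        c = lam / (1.0 + lam * self.ni)
        A = self.XtX - (self.Sx * c[:, None]).T @ self.Sx
        b = self.Xty - self.Sx.T @ (c * self.sy)
        cho = linalg.cho_factor(A, lower=True, check_finite=False)
        beta = linalg.cho_solve(cho, b, check_finite=False)
        quad = self.yty - float(c @ (self.sy**2)) - float(beta @ b)
        quad = max(quad, 1e-300)
        logdetV = float(np.log1p(lam * self.ni).sum())
        logdetA = 2.0 * float(np.log(np.diag(cho[0])).sum())
        return beta, quad, logdetV, logdetA, cho

    def loglik(self, lam: float, reml: bool) -> float:
        _, quad, logdetV, logdetA, _ = self._components(lam)
        df = self.n - self.p if reml else self.n
        ll = -0.5 * (df * (math.log(quad / df) + 1.0 + _LOG2PI) + logdetV)
        if reml:
            ll -= 0.5 * logdetA
        return ll

    def fit(self, reml: bool = True):
        """Profile the (restricted) likelihood over log(lambda)."""
        lo, hi = _LOG_LAMBDA_BOUNDS

        def nll(t: float) -> float:
            try:
                return -self.loglik(math.exp(t), reml)
            except linalg.LinAlgError:
                return math.inf

        res = optimize.minimize_scalar(
            nll, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10, "maxiter": 500},
        )
        ll_hat = -res.fun
        ll_zero = -nll(lo)  # effectively lambda = 0
        if not np.isfinite(ll_hat) and not np.isfinite(ll_zero):
            raise ConvergenceError("profiled likelihood not finite anywhere")
        boundary = (ll_zero >= ll_hat - 1e-9) or (res.x <= lo + 1e-6)
        lam = 0.0 if boundary else float(math.exp(res.x))
        beta, quad, _, _, cho = self._components(lam)
        df = self.n - self.p if reml else self.n
        v_res = quad / df
        v_id = lam * v_res
        ll = self.loglik(lam, reml)
        cov_beta = v_res * linalg.cho_solve(
            cho, np.eye(self.p), check_finite=False
        )
        se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
        converged = bool(res.success or boundary)
        return lam, beta, se, v_id, v_res, ll, converged


class _OLSDesign:
    """Plain least-squares counterpart used when there is no random term."""

    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.X = X
        self.n, self.p = X.shape
        self.set_y(y)

    def set_y(self, y: np.ndarray, presorted: bool = False) -> None:
        self.y = y

    def fit(self, reml: bool = True):
        beta, rss, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        resid = self.y - self.X @ beta
        rss = float(resid @ resid)
        df = self.n - self.p if reml else self.n
        v_res = rss / df
        ll = -0.5 * df * (math.log(rss / df) + 1.0 + _LOG2PI)
        if reml:
            sign, logdetA = np.linalg.slogdet(self.X.T @ self.X)
            ll -= 0.5 * logdetA
        cov = v_res * np.linalg.inv(self.X.T @ self.X)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        return 0.0, beta, se, 0.0, v_res, ll, True

    @property
    def rss(self) -> float:
        beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        r = self.y - self.X @ beta
        return float(r @ r)


# ---------------------------------------------------------------------------
# Public fit object and operations
# ---------------------------------------------------------------------------

@dataclass
class FittedLMM:
    """REML fit of a random-intercept model (or OLS fit when no random term)."""

    spec: ModelSpec
    beta: pd.Series
    se: pd.Series
    V_ID: float
    V_res: float
    reml_loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    lambda_: float
    colnames: list[str] = field(repr=False, default_factory=list)
    term_cols: dict[str, list[int]] = field(repr=False, default_factory=dict)
    _engine: object = field(repr=False, default=None)
    _data: pd.DataFrame = field(repr=False, default=None)

    @property
    def is_mixed(self) -> bool:
        return self.spec.random_group is not None

    @property
    def fitted_fixed(self) -> np.ndarray:
        return self._engine.X @ self.beta.to_numpy()


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> FittedLMM:
    """Fit ``spec`` to ``data`` by profiled REML (OLS if no random term)."""
    X, y, names, term_cols, cc = build_design(data, spec)
    if len(y) < X.shape[1] + 2:
        raise InsufficientDataError(
            f"{len(y)} complete-case rows for {X.shape[1]} parameters"
        )
    _check_rank(X, names)
    if spec.random_group is None:
        engine = _OLSDesign(X, y)
        n_groups = 0
    else:
        codes, levels = pd.factorize(cc[spec.random_group])
        if len(levels) < 2:
            raise ValidationError(
                f"random group {spec.random_group!r} needs >= 2 levels"
            )
        engine = _GroupedDesign(X, y, codes)
        n_groups = len(levels)
    lam, beta, se, v_id, v_res, ll, converged = engine.fit(reml=True)
    if not converged:
        raise ConvergenceError(f"REML fit did not converge for {spec.formula}")
    return FittedLMM(
        spec=spec,
        beta=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        V_ID=v_id,
        V_res=v_res,
        reml_loglik=ll,
        n_obs=engine.n,
        n_groups=n_groups,
        converged=converged,
        lambda_=lam,
        colnames=names,
        term_cols=term_cols,
        _engine=engine,
        _data=cc,
    )


def repeatability(fit: FittedLMM) -> float:
    """Intraclass correlation R = V_ID / (V_ID + V_res)."""
    if not fit.converged:
        raise ConvergenceError("repeatability requires a converged fit")
    tot = fit.V_ID + fit.V_res
    if tot <= 0:
        raise ValidationError("repeatability undefined: V_ID = V_res = 0")
    return fit.V_ID / tot


@dataclass(frozen=True)
class RepeatabilityEstimate:
    """Point estimate of R with a parametric-simulation percentile CI."""

    trait: str
    R: float
    ci_low: float
    ci_high: float
    n_sim: int
    kind: str  # "raw" or "adjusted"
    seed: int | None
    n_obs: int
    n_groups: int

    @property
    def significant(self) -> bool:
        """CI distinctly above zero."""
        return self.ci_low > 0.0


def simulate_ci(
    fit: FittedLMM,
    n_sim: int = 1000,
    seed: int | None = None,
    max_failure_frac: float = 0.2,
) -> RepeatabilityEstimate:
    """Percentile CI for R from ``n_sim`` parametric simulations of the model.

    Each replicate draws group effects ~ N(0, V_ID) and residuals
    ~ N(0, V_res) around the fitted fixed-effect surface, refits the same
    model by REML, and records R; the CI is the (2.5, 97.5) percentile pair
    (linear-interpolation / type-7 percentiles).
    """
    if not fit.is_mixed:
        raise ValidationError("simulation CI requires a random-intercept model")
    if n_sim < 2:
        raise ValidationError("n_sim must be >= 2")
    eng: _GroupedDesign = fit._engine
    rng = np.random.default_rng(seed)
    mu = eng.X @ fit.beta.to_numpy()
    sd_u = math.sqrt(max(fit.V_ID, 0.0))
    sd_e = math.sqrt(fit.V_res)
    group_idx = np.repeat(np.arange(eng.q), eng.ni.astype(int))
    y_orig = eng.y
    r_sims = []
    failures = 0
    try:
        for _ in range(n_sim):
            u = rng.normal(0.0, sd_u, eng.q)
            ystar = mu + u[group_idx] + rng.normal(0.0, sd_e, eng.n)
            try:
                eng.set_y(ystar, presorted=True)
                _, _, _, v_id, v_res, _, conv = eng.fit(reml=True)
                if not conv or v_id + v_res <= 0:
                    failures += 1
                    continue
                r_sims.append(v_id / (v_id + v_res))
            except (linalg.LinAlgError, ConvergenceError):
                failures += 1
    finally:
        eng.set_y(y_orig, presorted=True)
    if failures > max_failure_frac * n_sim:
        raise CIUnreliableError(
            f"{failures}/{n_sim} simulation refits failed; CI unreliable"
        )
    lo, hi = np.percentile(np.asarray(r_sims), [2.5, 97.5])
    return RepeatabilityEstimate(
        trait=fit.spec.response,
        R=repeatability(fit),
        ci_low=float(lo),
        ci_high=float(hi),
        n_sim=n_sim,
        kind="adjusted" if fit.spec.fixed_terms else "raw",
        seed=seed,
        n_obs=fit.n_obs,
        n_groups=fit.n_groups,
    )


# ---------------------------------------------------------------------------
# Fixed-effect tests, selection, R-squared
# ---------------------------------------------------------------------------

def _ml_loglik_for(fit: FittedLMM, drop: list[int] | None = None) -> float:
    """ML log-likelihood of the fitted design, optionally dropping columns."""
    eng = fit._engine
    X = eng.X if drop is None else np.delete(eng.X, drop, axis=1)
    if fit.is_mixed:
        sub = _GroupedDesign(X, eng.y, eng.codes)
        # rows already sorted by group; codes/ys re-sorted harmlessly (stable)
        *_, ll, conv = sub.fit(reml=False)
        if not conv:
            raise ConvergenceError("nested ML refit failed")
        return ll
    sub = _OLSDesign(X, eng.y)
    *_, ll, _ = sub.fit(reml=False)
    return ll


def fixed_effect_pvalues(fit: FittedLMM) -> pd.Series:
    """Per-term p-values.

    Mixed models: likelihood-ratio chi-square between ML fits with and
    without the term's columns.  Plain linear models: partial F-test.
    Terms whose nested refit fails are returned as NaN (flagged untestable).
    """
    out = {}
    if fit.is_mixed:
        ll_full = _ml_loglik_for(fit)
    for term, cols in fit.term_cols.items():
        k = len(cols)
        try:
            if fit.is_mixed:
                ll_red = _ml_loglik_for(fit, drop=cols)
                lr = max(2.0 * (ll_full - ll_red), 0.0)
                out[term] = float(stats.chi2.sf(lr, df=k))
            else:
                eng: _OLSDesign = fit._engine
                rss_f = eng.rss
                red = _OLSDesign(np.delete(eng.X, cols, axis=1), eng.y)
                df_res = eng.n - eng.p
                f = ((red.rss - rss_f) / k) / (rss_f / df_res)
                out[term] = float(stats.f.sf(max(f, 0.0), k, df_res))
        except (linalg.LinAlgError, ConvergenceError):
            out[term] = float("nan")
    return pd.Series(out, dtype=float)


def _interaction_parents(term: str) -> set[str]:
    return {p.strip() for p in term.split(":")} if ":" in term else set()


def _removable(spec: ModelSpec, protected: set[str]) -> list[str]:
    """Terms eligible for removal: not protected, and not a marginal term of
    an interaction still in the model (interactions tested first)."""
    active_parents: set[str] = set()
    for t in spec.fixed_terms:
        active_parents |= _interaction_parents(t)
    return [
        t for t in spec.fixed_terms
        if t not in protected and t not in active_parents
    ]


def stepwise_backward(
    data: pd.DataFrame,
    full_spec: ModelSpec,
    alpha: float = 0.05,
    protected: set[str] | frozenset[str] = frozenset(),
) -> tuple[ModelSpec, FittedLMM, list[tuple[str, float]]]:
    """Iteratively drop the least-significant removable term with p >= alpha.

    Ties on p are broken by term order in the spec.  Protected covariates are
    never removed; marginal terms are never removed while their interaction
    remains.  Returns the final spec, its REML fit, and the removal history
    as (term, p) pairs.
    """
    protected = set(protected)
    spec = full_spec
    fit = fit_lmm(data, spec)
    history: list[tuple[str, float]] = []
    while True:
        candidates = _removable(spec, protected)
        if not candidates:
            return spec, fit, history
        pvals = fixed_effect_pvalues(fit)
        cand = [(t, pvals[t]) for t in candidates if np.isfinite(pvals[t])]
        cand = [(t, p) for t, p in cand if p >= alpha]
        if not cand:
            return spec, fit, history
        worst = max(cand, key=lambda tp: tp[1])  # max() keeps first on ties
        spec = spec.without(worst[0])
        fit = fit_lmm(data, spec)
        history.append((worst[0], float(worst[1])))


def r2_nakagawa(fit: FittedLMM) -> tuple[float, float]:
    """(marginal, conditional) R^2 from the variance of the fixed-effect
    predictions and the fitted variance components."""
    if not fit.converged:
        raise ConvergenceError("R^2 requires a converged fit")
    yhat = fit.fitted_fixed
    var_f = float(np.var(yhat, ddof=1)) if len(yhat) > 1 else 0.0
    tot = var_f + fit.V_ID + fit.V_res
    return var_f / tot, (var_f + fit.V_ID) / tot


def partial_r2(fit: FittedLMM, term: str) -> float:
    """Variance uniquely attributable to ``term``.

    Plain LM: 1 - RSS_full / RSS_reduced, which equals t^2/(t^2 + df_res)
    for a single-column term.  Mixed model: drop in marginal R^2 when the
    term is removed (REML refit), floored at 0.
    """
    if term not in fit.term_cols:
        raise KeyError(f"term {term!r} not in fitted model")
    if fit.is_mixed:
        red_fit = fit_lmm(fit._data, fit.spec.without(term))
        full_m, _ = r2_nakagawa(fit)
        red_m, _ = r2_nakagawa(red_fit)
        return max(full_m - red_m, 0.0)
    eng: _OLSDesign = fit._engine
    rss_f = eng.rss
    red = _OLSDesign(np.delete(eng.X, fit.term_cols[term], axis=1), eng.y)
    rss_r = red.rss
    if rss_r <= 0:
        return 0.0
    return max(1.0 - rss_f / rss_r, 0.0)


def r2_ols(fit: FittedLMM) -> float:
    """Plain coefficient of determination for a no-random-term fit."""
    if fit.is_mixed:
        raise ValidationError("r2_ols is for plain linear models")
    eng: _OLSDesign = fit._engine
    tss = float(np.sum((eng.y - eng.y.mean()) ** 2))
    return 1.0 - eng.rss / tss if tss > 0 else 0.0


def summary_table(fit: FittedLMM) -> pd.DataFrame:
    """Coefficient table with Wald CIs plus per-term p and partial R^2."""
    pvals = fixed_effect_pvalues(fit) if fit.term_cols else pd.Series(dtype=float)
    rows = []
    col_term = {}
    for term, cols in fit.term_cols.items():
        for c in cols:
            col_term[c] = term
    for j, name in enumerate(fit.colnames):
        term = col_term.get(j, "(Intercept)")
        est, se = fit.beta.iloc[j], fit.se.iloc[j]
        rows.append(
            {
                "column": name,
                "term": term,
                "estimate": est,
                "se": se,
                "ci_low": est - 1.96 * se,
                "ci_high": est + 1.96 * se,
                "p": pvals.get(term, np.nan),
                "partial_r2": partial_r2(fit, term)
                if term in fit.term_cols else np.nan,
            }
        )
    return pd.DataFrame(rows)
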