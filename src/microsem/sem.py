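"""Observed-variable structural equation (path) models.

A path model over p observed variables is parameterised by an acyclic
coefficient matrix B and a residual covariance matrix Psi; the implied
covariance is Sigma(theta) = (I-B)^-1 Psi (I-B)^-T.  Estimation minimises
the ML discrepancy

    F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

by quasi-Newton from per-equation OLS starts, with T = (n-1) F_ML.  Because
faecal CLR/log data are generally non-Gaussian, a mean-scaled
(Satorra-Bentler-type) statistic T_sc = T / c is computed with the scaling
factor c estimated from the fourth-order moment matrix of the data; robust
CFI/TLI use the scaled statistics.  Model selection follows an explicit
ledger: an absolute-fit filter (chi-square p, CFI/TLI robust, RMSEA, SRMR,
GFI/AGFI, standardized residuals), then the GFI-AGFI gap, then AIC.

The binary treatment enters as an exogenous observed variable whose
variance is fixed at its sample value rather than estimated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConvergenceError, ValidationError

#: Acceptance thresholds of the model-selection ledger.
LEDGER_THRESHOLDS = {
    "p_sc": (">", 0.05),
    "cfi_robust": (">", 0.95),
    "tli_robust": (">", 0.95),
    "rmsea": ("<", 0.07),
    "srmr": ("<", 0.08),
    "gfi": (">", 0.95),
    "agfi": (">", 0.95),
    "max_abs_sr": ("<", 2.58),
}


@dataclass
class PathModel:
    """Directed path model: free edges, free residual covariances, fixed variances."""

    variables: tuple
    edges: tuple  # ((parent, child), ...) free entries of B
    residual_covs: tuple = ()  # ((a, b), ...) free off-diagonal Psi entries
    fixed_variances: dict = field(default_factory=dict)  # var -> fixed Psi value or None
    name: str = ""

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        self.edges = tuple((p, c) for p, c in self.edges)
        self.residual_covs = tuple(tuple(sorted(pair)) for pair in self.residual_covs)
        known = set(self.variables)
        for p, c in self.edges:
            if p not in known or c not in known:
                raise ValidationError(f"edge ({p}, {c}) references unknown variable")
        for a, b in self.residual_covs:
            if a not in known or b not in known or a == b:
                raise ValidationError(f"bad residual covariance pair ({a}, {b})")
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("path model must be acyclic")
        self._graph = g
        if not self.name:
            self.name = ";".join(f"{p}->{c}" for p, c in self.edges) or "null"

    # -- parameter bookkeeping --------------------------------------------
    @property
    def p(self) -> int:
        return len(self.variables)

    def free_variances(self) -> list:
        return [v for v in self.variables if v not in self.fixed_variances]

    def parameter_names(self) -> list:
        names = [f"{p}->{c}" for p, c in self.edges]
        names += [f"var({v})" for v in self.free_variances()]
        names += [f"cov({a},{b})" for a, b in self.residual_covs]
        return names

    @property
    def q(self) -> int:
        return len(self.edges) + len(self.free_variances()) + len(self.residual_covs)

    def df(self) -> int:
        # fixed variances are known constants, not estimated, so they do not
        # reduce the p(p+1)/2 moment count available to test the model
        return self.p * (self.p + 1) // 2 - self.q

    def parents(self, v: str) -> list:
        return list(self._graph.predecessors(v))

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = {v: i for i, v in enumerate(self.variables)}
        b = np.zeros((self.p, self.p))
        psi = np.zeros((self.p, self.p))
        k = 0
        for pnt, chd in self.edges:
            b[idx[chd], idx[pnt]] = theta[k]
            k += 1
        for v in self.free_variances():
            psi[idx[v], idx[v]] = theta[k]
            k += 1
        for v, val in self.fixed_variances.items():
            psi[idx[v], idx[v]] = val
        for a, bb in self.residual_covs:
            psi[idx[a], idx[bb]] = psi[idx[bb], idx[a]] = theta[k]
            k += 1
        return b, psi

    @classmethod
    def from_text(cls, text: str, variables=None, name: str = "", fixed_variances=None) -> "PathModel":
        """Parse an edge-list spec: one ``A -> B`` per line, ``A ~~ B`` for
        residual covariances; blank lines and ``#`` comments ignored."""
        edges, covs, seen = [], [], []
        for line in text.splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            if "->" in line:
                p, c = (s.strip() for s in line.split("->"))
                edges.append((p, c))
                seen += [p, c]
            elif "~~" in line:
                a, b = (s.strip() for s in line.split("~~"))
                covs.append((a, b))
                seen += [a, b]
            else:
                raise ValidationError(f"cannot parse model line {line!r}")
        if variables is None:
            variables = tuple(dict.fromkeys(seen))
        return cls(tuple(variables), tuple(edges), tuple(covs),
                   dict(fixed_variances or {}), name)


def implied_covariance(model: PathModel, theta: np.ndarray) -> np.ndarray:
    """Sigma(theta) = (I-B)^-1 Psi (I-B)^-T."""
    b, psi = model.matrices(theta)
    eye = np.eye(model.p)
    try:
        inv = np.linalg.inv(eye - b)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("(I - B) is singular") from exc
    sigma = inv @ psi @ inv.T
    return (sigma + sigma.T) / 2.0


# ---------------------------------------------------------------------------
# vech / duplication utilities (p <= 5, so dense construction is cheap)


def _vech_indices(p: int) -> list:
    return [(i, j) for j in range(p) for i in range(j, p)]


def _vech(mat: np.ndarray) -> np.ndarray:
    p = mat.shape[0]
    return np.array([mat[i, j] for i, j in _vech_indices(p)])


def _duplication(p: int) -> np.ndarray:
    pairs = _vech_indices(p)
    d = np.zeros((p * p, len(pairs)))
    for col, (i, j) in enumerate(pairs):
        d[i * p + j, col] = 1.0
        d[j * p + i, col] = 1.0
    return d


def _normal_weight(sigma_inv: np.ndarray, dup: np.ndarray) -> np.ndarray:
    return 0.5 * dup.T @ np.kron(sigma_inv, sigma_inv) @ dup


def _gamma_adf(x: np.ndarray) -> np.ndarray:
    """Fourth-order moment matrix of vech(S) (distribution-free estimate)."""
    n, p = x.shape
    z = x - x.mean(axis=0)
    pairs = _vech_indices(p)
    w = np.column_stack([z[:, i] * z[:, j] for i, j in pairs])
    s_b = w.mean(axis=0)  # biased covariances
    return (w.T @ w) / n - np.outer(s_b, s_b)


def _gamma_normal(sigma: np.ndarray) -> np.ndarray:
    pairs = _vech_indices(sigma.shape[0])
    g = np.zeros((len(pairs), len(pairs)))
    for a, (i, j) in enumerate(pairs):
        for b, (k, l) in enumerate(pairs):
            g[a, b] = sigma[i, k] * sigma[j, l] + sigma[i, l] * sigma[j, k]
    return g


# ---------------------------------------------------------------------------


@dataclass
class SEMFit:
    """One fitted path model with test statistics and the fit-index panel."""

    model: PathModel
    theta: np.ndarray
    se: np.ndarray
    s: np.ndarray
    sigma: np.ndarray
    n: int
    fmin: float
    t_stat: float
    t_scaled: float
    scaling: float
    df: int
    p_value: float
    p_scaled: float
    loglik: float
    aic: float
    converged: bool
    heywood: bool
    sr: np.ndarray
    indices: dict = field(default_factory=dict)
    boot_se: pd.DataFrame | None = None

    @property
    def estimates(self) -> pd.Series:
        return pd.Series(self.theta, index=self.model.parameter_names())

    def to_dict(self) -> dict:
        out = {
            "model": self.model.name,
            "variables": list(self.model.variables),
            "estimates": self.estimates.to_dict(),
            "se": dict(zip(self.model.parameter_names(), self.se.tolist())),
            "chisq": self.t_stat,
            "chisq_scaled": self.t_scaled,
            "scaling": self.scaling,
            "df": self.df,
            "p_value": self.p_value,
            "p_scaled": self.p_scaled,
            "loglik": self.loglik,
            "aic": self.aic,
            "converged": self.converged,
            "heywood": self.heywood,
            "indices": dict(self.indices),
        }
        if self.boot_se is not None:
            out["bootstrap"] = self.boot_se.to_dict(orient="index")
        return out

    def to_dot(self) -> str:
        from .tables import dag_to_dot

        idx = {v: i for i, v in enumerate(self.model.variables)}
        b = np.zeros((self.model.p, self.model.p))
        for k, (pnt, chd) in enumerate(self.model.edges):
            b[idx[chd], idx[pnt]] = self.theta[k]
        return dag_to_dot(self.model.variables, b, label=self.model.name)


def _ols_start(model: PathModel, s: np.ndarray) -> np.ndarray:
    """Per-equation OLS coefficients/residual variances computed from S."""
    idx = {v: i for i, v in enumerate(model.variables)}
    coef: dict = {}
    resvar: dict = {}
    for v in model.variables:
        pa = model.parents(v)
        if pa:
            pa_i = [idx[p] for p in pa]
            sxx = s[np.ix_(pa_i, pa_i)]
            sxy = s[pa_i, idx[v]]
            beta = np.linalg.solve(sxx, sxy)
            for p, bb in zip(pa, beta):
                coef[(p, v)] = bb
            resvar[v] = max(s[idx[v], idx[v]] - sxy @ beta, 1e-3)
        else:
            resvar[v] = s[idx[v], idx[v]]
    theta = [coef[e] for e in model.edges]
    theta += [resvar[v] for v in model.free_variances()]
    theta += [0.0 for _ in model.residual_covs]
    return np.array(theta, dtype=float)


def fit_ml(
    model: PathModel,
    data: pd.DataFrame,
    tol: float = 1e-10,
    max_iter: int = 500,
    robust: bool = True,
) -> SEMFit:
    """Maximum-likelihood fit with mean-scaled robust test statistic.

    ``robust=False`` skips the fourth-moment scaling, standard errors and
    residual diagnostics; bootstrap replicates only need point estimates.
    """
    x = data.loc[:, list(model.variables)].to_numpy(dtype=float)
    n, p = x.shape
    if n <= p:
        raise ValidationError("need more samples than variables")
    if (x.std(axis=0, ddof=1) == 0).any():
        raise ValidationError("zero-variance column in SEM data")
    s = np.cov(x, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(s) < p:
        raise ValidationError("sample covariance is singular")
    sign, logdet_s = np.linalg.slogdet(s)

    def discrepancy(theta: np.ndarray) -> float:
        try:
            sigma = implied_covariance(model, theta)
            c = np.linalg.cholesky(sigma)
        except (np.linalg.LinAlgError, ValidationError):
            return 1e10
        logdet = 2.0 * np.log(np.diag(c)).sum()
        inv = np.linalg.inv(sigma)
        return float(logdet + np.trace(s @ inv) - logdet_s - p)

    idx = {v: i for i, v in enumerate(model.variables)}

    def gradient(theta: np.ndarray) -> np.ndarray:
        # dF/dSigma = Sigma^-1 (Sigma - S) Sigma^-1; chain through
        # Sigma = A Psi A^T with A = (I - B)^-1
        b, psi = model.matrices(theta)
        try:
            a = np.linalg.inv(np.eye(p) - b)
            sigma = a @ psi @ a.T
            inv = np.linalg.inv(sigma)
        except np.linalg.LinAlgError:
            return optimize.approx_fprime(theta, discrepancy, 1e-7)
        g = inv @ (sigma - s) @ inv
        grad = np.empty(theta.size)
        k = 0
        for pnt, chd in model.edges:
            m = np.outer(a[:, idx[chd]], sigma[idx[pnt], :])
            grad[k] = 2.0 * float(np.sum(g * m))
            k += 1
        for v in model.free_variances():
            av = a[:, idx[v]]
            grad[k] = float(av @ g @ av)
            k += 1
        for va, vb in model.residual_covs:
            grad[k] = 2.0 * float(a[:, idx[va]] @ g @ a[:, idx[vb]])
            k += 1
        return grad

    theta0 = _ols_start(model, s)
    res = optimize.minimize(
        discrepancy, theta0, jac=gradient, method="BFGS",
        options={"gtol": 1e-8, "maxiter": max_iter},
    )
    grad_norm = float(np.linalg.norm(gradient(res.x)))
    # polish only if the quasi-Newton genuinely stalled away from a stationary
    # point (for recursive diagonal-Psi models the OLS start is already exact)
    if not res.success and res.fun > tol and grad_norm > 1e-5:
        res2 = optimize.minimize(discrepancy, res.x, method="Nelder-Mead",
                                 options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        if res2.fun < res.fun:
            res = res2
            grad_norm = float(np.linalg.norm(gradient(res.x)))
    theta = res.x
    fmin = max(float(res.fun), 0.0)
    converged = bool(res.fun < 1e9 and (res.success or grad_norm < 1e-3 or fmin < 1e-8))
    if not converged:
        raise ConvergenceError(f"SEM fit did not converge; |grad| = {grad_norm:.3e}")

    b, psi = model.matrices(theta)
    heywood = bool((np.diag(psi) < 0).any())
    if heywood:
        warnings.warn(f"Heywood case in model {model.name}: negative residual variance")

    sigma = implied_covariance(model, theta)
    df = model.df()
    t_stat = max((n - 1) * fmin, 0.0)

    if not robust:
        return SEMFit(
            model=model, theta=theta, se=np.full(theta.size, np.nan), s=s,
            sigma=sigma, n=n, fmin=fmin, t_stat=t_stat, t_scaled=t_stat,
            scaling=1.0, df=df,
            p_value=float(stats.chi2.sf(t_stat, df)) if df > 0 else 1.0,
            p_scaled=float(stats.chi2.sf(t_stat, df)) if df > 0 else 1.0,
            loglik=float("nan"), aic=float("nan"), converged=converged,
            heywood=heywood, sr=np.zeros((p, p)),
        )

    # robust scaling from fourth-order moments
    dup = _duplication(p)
    sigma_inv = np.linalg.inv(sigma)
    w = _normal_weight(sigma_inv, dup)
    delta = _numeric_delta(model, theta)
    wd = w @ delta
    try:
        bread = np.linalg.inv(delta.T @ w @ delta)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError("singular information matrix") from exc
    gamma = _gamma_adf(x)
    u = w - wd @ bread @ wd.T
    if df > 0:
        c_factor = float(np.trace(u @ gamma) / df)
        if not np.isfinite(c_factor) or c_factor <= 1e-8:
            c_factor = 1.0
    else:
        c_factor = 1.0
    t_scaled = t_stat / c_factor
    p_value = float(stats.chi2.sf(t_stat, df)) if df > 0 else 1.0
    p_scaled = float(stats.chi2.sf(t_scaled, df)) if df > 0 else 1.0

    se = np.sqrt(np.clip(np.diag(bread), 0.0, None) / (n - 1))

    loglik = -0.5 * (n - 1) * (
        float(np.linalg.slogdet(sigma)[1]) + float(np.trace(s @ sigma_inv))
        + p * np.log(2.0 * np.pi)
    )
    aic = -2.0 * loglik + 2.0 * model.q

    # standardized residuals: (s - sigma) / asymptotic SD of the residual
    gamma_nt = _gamma_normal(sigma)
    vres = (gamma_nt - delta @ bread @ delta.T) / (n - 1)
    resid_v = _vech(s - sigma)
    sd = np.sqrt(np.clip(np.diag(vres), 0.0, None))
    sr_v = np.where(sd > 1e-10, resid_v / np.where(sd > 1e-10, sd, 1.0), 0.0)
    sr = np.zeros((p, p))
    for val, (i, j) in zip(sr_v, _vech_indices(p)):
        sr[i, j] = sr[j, i] = val

    return SEMFit(
        model=model, theta=theta, se=se, s=s, sigma=sigma, n=n, fmin=fmin,
        t_stat=t_stat, t_scaled=t_scaled, scaling=c_factor, df=df,
        p_value=p_value, p_scaled=p_scaled, loglik=loglik, aic=aic,
        converged=converged, heywood=heywood, sr=sr,
    )


def _numeric_delta(model: PathModel, theta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """d vech(Sigma) / d theta by central differences."""
    cols = []
    for k in range(theta.size):
        up, dn = theta.copy(), theta.copy()
        up[k] += eps
        dn[k] -= eps
        cols.append((_vech(implied_covariance(model, up))
                     - _vech(implied_covariance(model, dn))) / (2 * eps))
    return np.column_stack(cols)


def independence_model(variables) -> PathModel:
    return PathModel(tuple(variables), (), (), {}, name="independence")


def fit_baseline(variables, data: pd.DataFrame) -> SEMFit:
    """Independence baseline: free variances, zero covariances."""
    return fit_ml(independence_model(variables), data)


def fit_indices(fit: SEMFit, baseline: SEMFit) -> dict:
    """Full fit-index panel; robust CFI/TLI use the mean-scaled statistics."""
    t, df, n = fit.t_stat, fit.df, fit.n
    t0, df0 = baseline.t_stat, baseline.df
    ts, t0s = fit.t_scaled, baseline.t_scaled

    def _cfi(tm, dfm, tb, dfb):
        num = max(tm - dfm, 0.0)
        den = max(tb - dfb, tm - dfm, 0.0)
        return 1.0 - num / den if den > 0 else 1.0

    def _tli(tm, dfm, tb, dfb):
        if dfm == 0 or dfb == 0:
            return float("nan")
        denom = tb / dfb - 1.0
        return (tb / dfb - tm / dfm) / denom if denom != 0 else float("nan")

    s, sigma = fit.s, fit.sigma
    p = s.shape[0]
    sigma_inv = np.linalg.inv(sigma)
    m = sigma_inv @ s
    gfi = 1.0 - np.trace((m - np.eye(p)) @ (m - np.eye(p))) / np.trace(m @ m)
    agfi = (
        1.0 - (p * (p + 1) / (2.0 * df)) * (1.0 - gfi) if df > 0 else float("nan")
    )
    dstd = np.sqrt(np.outer(np.diag(s), np.diag(s)))
    std_resid = (s - sigma) / dstd
    srmr = float(np.sqrt(np.mean(_vech(std_resid) ** 2)))
    if df > 0:
        rmsea = float(np.sqrt(max(t - df, 0.0) / (df * (n - 1))))
    else:
        # saturated model: zero discrepancy by construction, conventionally 0;
        # a df=0 model that somehow misfits has no defined RMSEA
        rmsea = 0.0 if t <= 1e-10 else float("nan")
    indices = {
        "chisq": t,
        "chisq_scaled": ts,
        "df": df,
        "p_value": fit.p_value,
        "p_sc": fit.p_scaled,
        "cfi": _cfi(t, df, t0, df0),
        "tli": _tli(t, df, t0, df0),
        "cfi_robust": _cfi(ts, df, t0s, df0),
        "tli_robust": _tli(ts, df, t0s, df0),
        "rmsea": rmsea,
        "srmr": srmr,
        "gfi": float(gfi),
        "agfi": float(agfi),
        "gfi_agfi_gap": float(gfi - agfi) if df > 0 else float("nan"),
        "aic": fit.aic,
        "max_abs_sr": float(np.abs(fit.sr).max()),
    }
    fit.indices = indices
    return indices


def bootstrap_se(
    model: PathModel,
    data: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Case-resampling bootstrap SEs and percentile 95% CIs per parameter."""
    if n_boot < 100:
        raise ValidationError("n_boot must be at least 100")
    x = data.loc[:, list(model.variables)]
    if (x.std(ddof=1) == 0).any():
        raise ValidationError("zero-variance column in bootstrap data")
    rng = np.random.default_rng(seed)
    n = len(x)
    draws, failed = [], 0
    for _ in range(n_boot):
        take = rng.integers(0, n, n)
        try:
            fit = fit_ml(model, x.iloc[take], robust=False)
            draws.append(fit.theta)
        except (ConvergenceError, ValidationError):
            failed += 1
    if failed > 0.2 * n_boot:
        raise ConvergenceError(
            f"{failed}/{n_boot} bootstrap replicates failed to converge"
        )
    arr = np.asarray(draws)
    lo, hi = np.percentile(arr, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "se": arr.std(axis=0, ddof=1),
            "ci_lo": lo,
            "ci_hi": hi,
            "n_converged": arr.shape[0],
        },
        index=model.parameter_names(),
    )


# ---------------------------------------------------------------------------
# candidate enumeration and the selection ledger


def enumerate_orientations(
    variables, skeleton_edges, exogenous: str = "Cmp", cap: int = 200
) -> list:
    """All acyclic orientations of an undirected skeleton, ``exogenous``
    forced to have no parents; capped at ``cap`` candidates."""
    out = []
    skeleton = [tuple(e) for e in skeleton_edges]
    for signs in product((0, 1), repeat=len(skeleton)):
        edges = tuple(
            (a, b) if s == 0 else (b, a) for (a, b), s in zip(skeleton, signs)
        )
        if any(c == exogenous for _, c in edges):
            continue
        try:
            out.append(PathModel(tuple(variables), edges))
        except ValidationError:
            continue
        if len(out) >= cap:
            break
    return out


def ledger_pass(indices: dict, thresholds: dict | None = None) -> dict:
    """Per-criterion pass/fail flags for the stage-1 absolute-fit filter."""
    thresholds = thresholds or LEDGER_THRESHOLDS
    flags = {}
    for key, (op, cut) in thresholds.items():
        val = indices.get(key, float("nan"))
        if np.isnan(val):
            flags[key] = False
        else:
            flags[key] = val > cut if op == ">" else val < cut
    return flags


@dataclass
class SelectionResult:
    """Ranking table over the candidate model space plus the selected fit."""

    table: pd.DataFrame
    selected: SEMFit | None
    fits: dict

    def to_frame(self) -> pd.DataFrame:
        return self.table


def enumerate_and_select(
    candidates: list,
    data: pd.DataFrame,
    thresholds: dict | None = None,
    gap_tol: float = 0.01,
) -> SelectionResult:
    """Fit every candidate and apply the three-stage acceptance ledger.

    Stage 1 keeps models passing every absolute-fit criterion; stage 2 keeps
    those whose GFI-AGFI gap is within ``gap_tol`` of the smallest gap among
    the passers; stage 3 selects the minimal AIC.  An empty stage-1 set
    yields ``selected=None`` with full per-model diagnostics.
    """
    if not candidates:
        raise ValidationError("no candidate models supplied")
    variables = candidates[0].variables
    baseline = fit_baseline(variables, data)
    rows, fits = [], {}
    for model in candidates:
        row: dict = {"model": model.name, "df": model.df()}
        try:
            fit = fit_ml(model, data)
            idx = fit_indices(fit, baseline)
            flags = ledger_pass(idx, thresholds)
            row.update(idx)
            row.update({f"pass_{k}": v for k, v in flags.items()})
            row["stage1"] = all(flags.values())
            row["error"] = ""
            fits[model.name] = fit
        except (ConvergenceError, ValidationError) as exc:
            row["stage1"] = False
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("model")

    passed = table[table["stage1"]]
    selected = None
    if not passed.empty:
        gaps = passed["gfi_agfi_gap"]
        min_gap = gaps.min()
        shortlist = passed[gaps <= min_gap + gap_tol]
        best = shortlist.sort_values(["aic", "gfi_agfi_gap"], kind="stable").index[0]
        selected = fits[best]
        table["selected"] = [m == best for m in table.index]
    else:
        table["selected"] = False
    return SelectionResult(table=table, selected=selected, fits=fits)


def group_compare(values, arm_labels) -> dict:
    """Wilcoxon rank-sum comparison of one component between two arms.

    Exact null distribution when both arms have n <= 10 and there are no
    ties; normal approximation with tie correction otherwise.
    """
    v = np.asarray(values, dtype=float)
    labs = np.asarray(arm_labels)
    arms = np.unique(labs)
    if arms.size != 2:
        raise ValidationError("group_compare needs exactly two arms")
    a = v[labs == arms[0]]
    b = v[labs == arms[1]]
    if min(a.size, b.size) < 3:
        raise ValidationError("each arm needs at least 3 samples")
    has_ties = np.unique(v).size < v.size
    method = "exact" if (max(a.size, b.size) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "arms": (str(arms[0]), str(arms[1])),
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "method": method,
        "median_diff": float(np.median(a) - np.median(b)),
    }
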