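"""Causal mediation and linear non-Gaussian causal discovery.

Mediation follows the classical two-regression decomposition: with
mediator ~ treatment and outcome ~ treatment + mediator fitted by least
squares, the average causal mediation effect (ACME) is the product a*b of
the treatment->mediator and mediator->outcome coefficients, the average
direct effect (ADE) is the residual treatment coefficient c', and in the
linear no-interaction case ACME + ADE equals the total effect exactly.
Uncertainty comes from a case-resampling bootstrap with percentile CIs.

DirectLiNGAM identifies a causal order of a linear non-Gaussian acyclic
model by repeatedly extracting the most exogenous variable: the candidate
whose pairwise likelihood-ratio measure, built from the maximum-entropy
negentropy approximation (log-cosh and Gaussian-moment terms), shows its
residuals most independent of it.  Coefficients are then estimated by
least squares respecting the order and pruned by per-coefficient t tests.

The Bayesian route scores every labeled DAG on up to four variables: each
variable is linear in its parents with a two-component Gaussian-mixture
error (free component means, so sub-Gaussian error densities such as the
uniform are representable), the marginal likelihood is approximated by a
Laplace expansion around the posterior mode, and a uniform DAG prior
yields a normalized posterior over structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ValidationError

# maximum-entropy negentropy approximation constants
K1 = 79.047
K2 = 7.4129
GAMMA = 0.37457


# ---------------------------------------------------------------------------
# mediation


@dataclass
class MediationResult:
    """ACME/ADE decomposition with bootstrap percentile intervals."""

    treatment: str
    mediator: str
    outcome: str
    acme: float
    ade: float
    total: float
    prop_mediated: float
    ci: dict  # name -> (lo, hi)
    n_sims: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "treatment": self.treatment,
            "mediator": self.mediator,
            "outcome": self.outcome,
            "acme": self.acme,
            "ade": self.ade,
            "total": self.total,
            "prop_mediated": self.prop_mediated,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "n_sims": self.n_sims,
            "seed": self.seed,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, val in (
            ("acme", self.acme),
            ("ade", self.ade),
            ("total", self.total),
            ("prop_mediated", self.prop_mediated),
        ):
            lo, hi = self.ci[name]
            rows.append({"effect": name, "estimate": val, "ci_lo": lo, "ci_hi": hi})
        return pd.DataFrame(rows).set_index("effect")

    def significant(self, name: str = "acme") -> bool:
        lo, hi = self.ci[name]
        return not (lo <= 0.0 <= hi)


def _ols(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(y)), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return beta


def _mediation_effects(t, m, y, cov) -> tuple[float, float, float]:
    xm = np.column_stack([t] + cov)
    a = _ols(m, xm)[1]
    xy = np.column_stack([t, m] + cov)
    by = _ols(y, xy)
    cprime, b = by[1], by[2]
    return a * b, cprime, a * b + cprime


def mediate(
    data: pd.DataFrame,
    treatment: str,
    mediator: str,
    outcome: str,
    covariates: tuple = (),
    n_sims: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Linear no-interaction causal mediation with bootstrap CIs."""
    if n_sims < 100:
        raise ValidationError("n_sims must be at least 100")
    t = data[treatment].to_numpy(dtype=float)
    m = data[mediator].to_numpy(dtype=float)
    y = data[outcome].to_numpy(dtype=float)
    cov = [data[c].to_numpy(dtype=float) for c in covariates]
    r = np.corrcoef(t, m)[0, 1] ** 2
    if r > 0.999:
        raise ValidationError("mediator is collinear with treatment (R^2 > 0.999)")

    acme, ade, total = _mediation_effects(t, m, y, cov)
    rng = np.random.default_rng(seed)
    n = len(t)
    draws = np.empty((n_sims, 4))
    for k in range(n_sims):
        take = rng.integers(0, n, n)
        a_, d_, tot_ = _mediation_effects(
            t[take], m[take], y[take], [c[take] for c in cov]
        )
        draws[k] = (a_, d_, tot_, a_ / tot_ if tot_ != 0 else np.nan)
    lo, hi = np.nanpercentile(draws, [2.5, 97.5], axis=0)
    ci = {
        name: (float(lo[j]), float(hi[j]))
        for j, name in enumerate(("acme", "ade", "total", "prop_mediated"))
    }
    return MediationResult(
        treatment=treatment,
        mediator=mediator,
        outcome=outcome,
        acme=float(acme),
        ade=float(ade),
        total=float(total),
        prop_mediated=float(acme / total) if total != 0 else float("nan"),
        ci=ci,
        n_sims=n_sims,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# DirectLiNGAM


def _entropy_maxent(u: np.ndarray) -> float:
    """Differential entropy of a standardized variable (maxent approximation)."""
    return (
        0.5 * (1.0 + np.log(2.0 * np.pi))
        - K1 * (np.mean(np.log(np.cosh(u))) - GAMMA) ** 2
        - K2 * np.mean(u * np.exp(-(u**2) / 2.0)) ** 2
    )


def _std(u: np.ndarray) -> np.ndarray:
    sd = u.std()
    if sd == 0:
        raise ValidationError("constant column in LiNGAM input")
    return (u - u.mean()) / sd


def _pair_measure(xi: np.ndarray, xj: np.ndarray) -> float:
    """Likelihood-ratio style measure: positive favours xi -> xj."""
    ri_j = xi - np.dot(xi, xj) / np.dot(xj, xj) * xj  # residual of xi on xj
    rj_i = xj - np.dot(xj, xi) / np.dot(xi, xi) * xi
    return (
        _entropy_maxent(xj) + _entropy_maxent(_std(ri_j))
        - _entropy_maxent(xi) - _entropy_maxent(_std(rj_i))
    )


def direct_lingam(data: pd.DataFrame, prune_alpha: float = 0.05) -> tuple[list, pd.DataFrame]:
    """DirectLiNGAM causal order plus t-test-pruned weighted adjacency.

    Returns ``(order, B)`` where ``order`` lists column names from most to
    least exogenous and ``B.loc[child, parent]`` is the least-squares
    coefficient (zero where pruned at ``prune_alpha``).
    """
    cols = list(data.columns)
    if len(cols) < 2:
        raise ValidationError("direct_lingam needs at least 2 variables")
    x = data.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 10 * len(cols):
        warnings.warn("fewer than 10 samples per variable; order may be unstable")
    x = np.column_stack([_std(x[:, j]) for j in range(x.shape[1])])
    remaining = list(range(len(cols)))
    order: list[int] = []
    work = x.copy()
    while len(remaining) > 1:
        scores = {}
        for i in remaining:
            xi = _std(work[:, i])
            total = 0.0
            for j in remaining:
                if j == i:
                    continue
                m = _pair_measure(xi, _std(work[:, j]))
                total += min(0.0, m) ** 2
            scores[i] = total
        root = min(remaining, key=lambda i: (scores[i], i))
        order.append(root)
        remaining.remove(root)
        xr = _std(work[:, root])
        for j in remaining:
            xj = work[:, j]
            work[:, j] = xj - np.dot(xj, xr) / np.dot(xr, xr) * xr
    order.append(remaining[0])

    # least-squares B respecting the order, then t-test pruning
    b = pd.DataFrame(0.0, index=cols, columns=cols)
    raw = data.to_numpy(dtype=float)
    for pos, child in enumerate(order):
        parents = order[:pos]
        if not parents:
            continue
        design = np.column_stack([np.ones(n)] + [raw[:, p] for p in parents])
        beta, res, rank, _ = np.linalg.lstsq(design, raw[:, child], rcond=None)
        resid = raw[:, child] - design @ beta
        dof = n - design.shape[1]
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(design.T @ design)
        for k, p_idx in enumerate(parents, start=1):
            tval = beta[k] / np.sqrt(cov[k, k])
            pval = 2.0 * stats.t.sf(abs(tval), dof)
            if pval < prune_alpha:
                b.iloc[child, p_idx] = beta[k]
    return [cols[i] for i in order], b


# ---------------------------------------------------------------------------
# DAG enumeration and Bayesian scoring


def enumerate_dags(n_vars: int) -> list:
    """Every labeled DAG on ``n_vars`` nodes as a tuple of (parent, child)
    index edges; counts follow 1, 3, 25, 543 for 1-4 nodes."""
    if not (1 <= n_vars <= 5):
        raise ValidationError("enumerate_dags supports 1..5 variables")
    pairs = list(combinations(range(n_vars), 2))
    dags = []
    # each unordered pair is absent, forward or backward; filter cyclic
    for states in product((0, 1, 2), repeat=len(pairs)):
        edges = []
        for (a, b), s in zip(pairs, states):
            if s == 1:
                edges.append((a, b))
            elif s == 2:
                edges.append((b, a))
        if _is_acyclic(n_vars, edges):
            dags.append(tuple(sorted(edges)))
    return dags


def _is_acyclic(n: int, edges: list) -> bool:
    children: dict = {i: [] for i in range(n)}
    indeg = {i: 0 for i in range(n)}
    for a, b in edges:
        children[a].append(b)
        indeg[b] += 1
    queue = [i for i in range(n) if indeg[i] == 0]
    seen = 0
    while queue:
        v = queue.pop()
        seen += 1
        for c in children[v]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    return seen == n


@dataclass
class DAGPosterior:
    """Normalized posterior over every DAG on the variable subset."""

    variables: tuple
    dags: list  # list of (edges, log_score, probability), sorted descending
    top_k: int = 6

    def __post_init__(self) -> None:
        total = sum(p for _, _, p in self.dags)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("posterior probabilities must sum to 1")

    @property
    def top_mass(self) -> float:
        return float(sum(p for _, _, p in self.dags[: self.top_k]))

    def best(self) -> tuple:
        return self.dags[0][0]

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "top_k": self.top_k,
            "top_mass": self.top_mass,
            "dags": [
                {
                    "edges": [
                        f"{self.variables[a]}->{self.variables[b]}" for a, b in edges
                    ],
                    "log_score": ls,
                    "probability": p,
                }
                for edges, ls, p in self.dags
            ],
        }

    def to_dot(self) -> str:
        from .tables import dag_to_dot

        blocks = []
        k = len(self.variables)
        for rank, (edges, _, prob) in enumerate(self.dags[: self.top_k], start=1):
            adj = np.zeros((k, k))
            for a, b in edges:
                adj[b, a] = 1.0
            blocks.append(
                dag_to_dot(
                    [f"{v}_{rank}" for v in self.variables],
                    adj,
                    label=f"rank {rank}: {100.0 * prob:.2f}%",
                )
            )
        return "\n".join(blocks)


def _family_log_marginal(y: np.ndarray, parents: np.ndarray, cache: dict, key) -> float:
    """Laplace-approximated log marginal likelihood of one variable given
    its parents under the Gaussian-mixture error model."""
    if key in cache:
        return cache[key]
    n = y.size
    k = parents.shape[1]

    def unpack(th):
        b = th[:k]
        w = 1.0 / (1.0 + np.exp(-th[k]))
        mu1, mu2 = th[k + 1], th[k + 2]
        s1 = np.exp(th[k + 3])
        s2 = np.exp(th[k + 4])
        return b, w, mu1, mu2, s1, s2

    def neg_log_post(th):
        b, w, mu1, mu2, s1, s2 = unpack(th)
        e = y - parents @ b if k else y
        comp1 = w * np.exp(-0.5 * (e - mu1) ** 2 / s1) / np.sqrt(2.0 * np.pi * s1)
        comp2 = (1.0 - w) * np.exp(-0.5 * (e - mu2) ** 2 / s2) / np.sqrt(2.0 * np.pi * s2)
        ll = np.log(np.maximum(comp1 + comp2, 1e-300)).sum()
        # priors: b ~ N(0,1); component means ~ N(0,1) (free means let the
        # mixture represent sub-Gaussian, e.g. uniform, errors); log-variances
        # ~ N(0, 2^2), a smooth weakly informative stand-in for a scaled
        # inverse-chi-square; w flat via the logistic Jacobian
        lp = -0.5 * float(b @ b) - 0.5 * (mu1**2 + mu2**2)
        lp += -0.5 * (th[k + 3] ** 2 + th[k + 4] ** 2) / 4.0
        lp += np.log(w) + np.log(1.0 - w)  # Jacobian of the logit transform
        return -(ll + lp)

    best = None
    for mean_split, var_split in ((0.7, -0.7), (0.0, 0.7), (1.2, -1.5)):
        th_try = np.zeros(k + 5)
        th_try[k + 1], th_try[k + 2] = -mean_split, mean_split
        th_try[k + 3], th_try[k + 4] = var_split, -var_split
        res = optimize.minimize(neg_log_post, th_try, method="BFGS",
                                options={"gtol": 1e-6, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    d = k + 5
    hess = _numeric_hessian(neg_log_post, best.x)
    sign, logdet = np.linalg.slogdet(hess)
    if sign <= 0:
        # flat direction (collapsed mixture): regularize the curvature
        hess = hess + np.eye(d) * 1e-3
        sign, logdet = np.linalg.slogdet(hess)
        if sign <= 0:
            cache[key] = -np.inf
            return -np.inf
    log_ml = -best.fun + 0.5 * d * np.log(2.0 * np.pi) - 0.5 * logdet
    cache[key] = float(log_ml)
    return cache[key]


def _numeric_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    d = x.size
    h = np.zeros((d, d))
    f0 = f(x)
    for i in range(d):
        for j in range(i, d):
            xi = x.copy(); xi[i] += eps
            xj = x.copy(); xj[j] += eps
            xij = x.copy(); xij[i] += eps; xij[j] += eps
            h[i, j] = h[j, i] = (f(xij) - f(xi) - f(xj) + f0) / eps**2
    return (h + h.T) / 2.0


def bayes_lingam(
    data: pd.DataFrame,
    variables: tuple | None = None,
    top_k: int = 6,
    seed: int = 0,
) -> DAGPosterior:
    """Posterior over all labeled DAGs on <= 4 variables.

    Data are standardized internally; the posterior is invariant to affine
    rescaling of any column.  Family scores (variable given parent set) are
    cached, so the exhaustive enumeration costs #vars * 2^(#vars-1)
    optimizations rather than one per DAG edge set.
    """
    cols = list(data.columns if variables is None else variables)
    if not (2 <= len(cols) <= 4):
        raise ValidationError("bayes_lingam supports 2..4 variables")
    x = data.loc[:, cols].to_numpy(dtype=float)
    for j in range(x.shape[1]):
        if x[:, j].std() == 0:
            raise ValidationError("constant column in bayes_lingam input")
    corr = np.corrcoef(x, rowvar=False)
    off = np.abs(corr - np.eye(len(cols)))
    if (off > 0.999).any():
        raise ValidationError("duplicate (collinear) columns in bayes_lingam input")
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)

    dags = enumerate_dags(len(cols))
    cache: dict = {}
    scores = []
    for edges in dags:
        total = 0.0
        for v in range(len(cols)):
            pa = tuple(sorted(a for a, b in edges if b == v))
            key = (v, pa)
            total += _family_log_marginal(x[:, v], x[:, list(pa)], cache, key)
        scores.append(total)
    scores = np.asarray(scores)
    if not np.isfinite(scores).any():
        raise ValidationError("every DAG scored at -inf; data degenerate")
    finite = np.where(np.isfinite(scores), scores, -np.inf)
    mx = finite.max()
    w = np.exp(finite - mx)
    prob = w / w.sum()
    ranked = sorted(
        zip(dags, scores, prob), key=lambda t: (-t[2], t[0])
    )
    return DAGPosterior(
        variables=tuple(cols),
        dags=[(e, float(s), float(p)) for e, s, p in ranked],
        top_k=top_k,
    )
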