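"""Exploratory factor analysis: minres extraction, promax rotation, VSS.

The extraction minimises the sum of squared off-diagonal residuals of
R - Lambda Lambda' over the uniquenesses (minimum-residual or "minres"
method): for a trial uniqueness vector the loadings are the scaled leading
eigenvectors of the reduced correlation matrix, and the uniquenesses are
optimised by quasi-Newton within (0.005, 1).

Rotation follows the classical two-step promax: varimax with Kaiser row
normalisation, then a least-squares oblique transformation toward the
element-wise power-kappa target.  The factor-number choice uses the very
simple structure (VSS) criterion: loadings simplified to the c largest
entries per row, scored by one minus the ratio of residual to total
off-diagonal mean square.

By default the analysis runs on a Spearman correlation matrix, and the
rotation is picked automatically: oblique (promax) when any off-diagonal
|rho| exceeds 0.4, orthogonal (varimax) otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ConvergenceError, ValidationError

PSI_LO, PSI_HI = 0.005, 1.0


@dataclass
class EFAResult:
    """Pattern loadings, factor correlations and per-feature diagnostics."""

    loadings: pd.DataFrame  # features x factors (pattern matrix)
    phi: np.ndarray  # factor correlation matrix
    uniquenesses: np.ndarray
    nfactors: int
    rotation: str
    vss_curve: dict = field(default_factory=dict)
    converged: bool = True

    @property
    def h2(self) -> pd.Series:
        lam = self.loadings.to_numpy()
        return pd.Series(
            np.diag(lam @ self.phi @ lam.T), index=self.loadings.index, name="h2"
        )

    @property
    def u2(self) -> pd.Series:
        return (1.0 - self.h2).rename("u2")

    @property
    def com(self) -> pd.Series:
        return complexity_scores(self.loadings)

    def implied_correlation(self) -> np.ndarray:
        lam = self.loadings.to_numpy()
        common = lam @ self.phi @ lam.T
        out = common.copy()
        np.fill_diagonal(out, 1.0)
        return out

    def to_frame(self) -> pd.DataFrame:
        frame = self.loadings.copy()
        frame.columns = [f"MR{j + 1}" for j in range(frame.shape[1])]
        frame["h2"] = self.h2
        frame["u2"] = self.u2
        frame["com"] = self.com
        return frame

    def to_dict(self) -> dict:
        return {
            "nfactors": self.nfactors,
            "rotation": self.rotation,
            "phi": self.phi.tolist(),
            "vss_curve": {str(k): v for k, v in self.vss_curve.items()},
            "loadings": self.loadings.to_dict(orient="index"),
        }


def _as_corr(x) -> tuple[np.ndarray, list]:
    if isinstance(x, pd.DataFrame):
        names = list(x.columns)
        arr = x.to_numpy(dtype=float)
    else:
        arr = np.asarray(x, dtype=float)
        names = [f"V{i + 1}" for i in range(arr.shape[1])]
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-8):
        raise ValidationError("expected a square symmetric correlation matrix")
    if not np.allclose(np.diag(arr), 1.0, atol=1e-6):
        raise ValidationError("correlation matrix must have unit diagonal")
    if np.linalg.eigvalsh(arr).min() < -1e-6:
        raise ValidationError("correlation matrix is not positive semi-definite")
    return arr, names


def _loadings_given_psi(corr: np.ndarray, psi: np.ndarray, m: int) -> np.ndarray:
    reduced = corr - np.diag(psi)
    vals, vecs = np.linalg.eigh(reduced)
    order = np.argsort(vals)[::-1][:m]
    lam = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
    return lam


def _offdiag_sq(mat: np.ndarray) -> float:
    off = mat - np.diag(np.diag(mat))
    return float((off**2).sum())


def _fix_signs(lam: np.ndarray) -> np.ndarray:
    lam = lam.copy()
    for j in range(lam.shape[1]):
        k = np.argmax(np.abs(lam[:, j]))
        if lam[k, j] < 0:
            lam[:, j] *= -1.0
    return lam


def fit_minres(corr, nfactors: int, tol: float = 1e-8, max_iter: int = 1000) -> EFAResult:
    """Unrotated minres factor solution of a correlation matrix."""
    r, names = _as_corr(corr)
    p = r.shape[0]
    if not (1 <= nfactors < p):
        raise ValidationError(f"nfactors must lie in [1, {p - 1}]")

    def objective(psi: np.ndarray) -> float:
        lam = _loadings_given_psi(r, psi, nfactors)
        return _offdiag_sq(r - lam @ lam.T)

    # start at 1 - squared multiple correlation, the classical warm start
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(r))
    except np.linalg.LinAlgError:
        smc = np.full(p, 0.5)
    psi0 = np.clip(1.0 - smc, PSI_LO, PSI_HI)
    res = optimize.minimize(
        objective,
        psi0,
        method="L-BFGS-B",
        bounds=[(PSI_LO, PSI_HI)] * p,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
    )
    if not res.success and res.fun > 1e-4:
        raise ConvergenceError(
            f"minres did not converge: {res.message}; residual {res.fun:.3e}"
        )
    lam = _fix_signs(_loadings_given_psi(r, res.x, nfactors))
    frame = pd.DataFrame(lam, index=names, columns=[f"F{j + 1}" for j in range(nfactors)])
    return EFAResult(
        loadings=frame,
        phi=np.eye(nfactors),
        uniquenesses=res.x,
        nfactors=nfactors,
        rotation="none",
        converged=bool(res.success),
    )


def varimax(loadings: np.ndarray, normalize: bool = True, tol: float = 1e-10,
            max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation; returns (rotated loadings, rotation matrix)."""
    lam = np.asarray(loadings, dtype=float).copy()
    p, m = lam.shape
    if m < 2:
        return lam, np.eye(1)
    h = np.sqrt((lam**2).sum(axis=1))
    if normalize:
        nz = h > 0
        lam[nz] = lam[nz] / h[nz, None]
    rot = np.eye(m)
    d_old = 0.0
    for _ in range(max_iter):
        b = lam @ rot
        grad = lam.T @ (b**3 - b @ np.diag((b**2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(grad)
        rot = u @ vt
        d = s.sum()
        if d_old != 0 and (d - d_old) < tol * d:
            break
        d_old = d
    out = lam @ rot
    if normalize:
        out = out * h[:, None]
    return out, rot


def promax_rotate(loadings, kappa: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Promax oblique rotation; returns (pattern matrix, factor correlation).

    kappa=1 degenerates to the (Kaiser-normalised) varimax solution with an
    identity factor correlation.
    """
    lam = np.asarray(loadings, dtype=float)
    if kappa < 1:
        raise ValidationError("kappa must be >= 1")
    if lam.shape[1] < 2:
        warnings.warn("promax with a single factor is the identity")
        return lam.copy(), np.eye(1)
    a, _ = varimax(lam)
    with np.errstate(invalid="ignore"):
        target = a * np.abs(a) ** (kappa - 1.0)
    u, *_ = np.linalg.lstsq(a, target, rcond=None)
    d = np.diag(np.linalg.inv(u.T @ u))
    u = u * np.sqrt(d)[None, :]
    pattern = a @ u
    phi = np.linalg.inv(u.T @ u)
    pattern = _fix_signs(pattern)
    # re-apply the sign convention consistently to phi
    signs = np.ones(pattern.shape[1])
    raw = a @ u
    for j in range(raw.shape[1]):
        k = np.argmax(np.abs(raw[:, j]))
        signs[j] = 1.0 if raw[k, j] >= 0 else -1.0
    phi = phi * np.outer(signs, signs)
    np.fill_diagonal(phi, 1.0)
    return pattern, phi


def complexity_scores(pattern) -> pd.Series:
    """Hofmann row complexity (sum lam^2)^2 / sum lam^4 per feature."""
    if isinstance(pattern, pd.DataFrame):
        index = pattern.index
        lam = pattern.to_numpy(dtype=float)
    else:
        lam = np.asarray(pattern, dtype=float)
        index = pd.RangeIndex(lam.shape[0])
    sq = lam**2
    num = sq.sum(axis=1) ** 2
    den = (sq**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        com = np.where(den > 0, num / den, np.nan)
    if np.isnan(com).any():
        warnings.warn("all-zero loading rows have undefined complexity")
    return pd.Series(com, index=index, name="com")


def _simplify(lam: np.ndarray, c: int) -> np.ndarray:
    out = np.zeros_like(lam)
    for i in range(lam.shape[0]):
        keep = np.argsort(np.abs(lam[i]))[::-1][:c]
        out[i, keep] = lam[i, keep]
    return out


def vss_curve(
    corr, max_nfactors: int, complexity_c: int = 1, plateau_tol: float = 0.2
) -> tuple[dict, int]:
    """Very-simple-structure criterion over candidate factor counts.

    For each k the fitted loadings (varimax-rotated for k >= 2) are
    simplified to the ``complexity_c`` largest entries per row and
    VSS_k = 1 - MS(residual of simplified model) / MS(off-diagonal R).

    Selection uses a plateau rule rather than the raw argmax: the smallest
    k that no larger candidate improves upon by more than ``plateau_tol``.
    Surplus factors always absorb a little sampling noise, so the raw curve
    drifts upward and its argmax overfactors; genuine common factors raise
    VSS by far more than the tolerance.
    """
    r, _ = _as_corr(corr)
    p = r.shape[0]
    if max_nfactors > p // 2:
        raise ValidationError("max_nfactors must not exceed #features / 2")
    denom = _offdiag_sq(r)
    curve: dict[int, float] = {}
    for k in range(1, max_nfactors + 1):
        try:
            fit = fit_minres(r, k)
        except (ConvergenceError, ValidationError):
            continue  # reported as missing; selection over the rest
        lam = fit.loadings.to_numpy()
        if k >= 2:
            lam, _ = varimax(lam)
        simple = _simplify(lam, complexity_c)
        resid = r - simple @ simple.T
        curve[k] = 1.0 - _offdiag_sq(resid) / denom
    if not curve:
        raise ConvergenceError("no candidate factor count could be fitted")
    best = None
    for k in sorted(curve):
        later = [curve[j] for j in curve if j > k]
        if not later or max(later) - curve[k] <= plateau_tol:
            best = k
            break
    return curve, best


def fit_efa(
    corr,
    nfactors: int,
    rotation: str = "auto",
    kappa: float = 4.0,
    vss_max: int | None = None,
    complexity_c: int = 1,
) -> EFAResult:
    """Full EFA: minres extraction plus the configured rotation.

    ``rotation='auto'`` applies the oblique-versus-orthogonal decision rule:
    promax when any off-diagonal |r| of the input exceeds 0.4, varimax
    otherwise.
    """
    r, _ = _as_corr(corr)
    fit = fit_minres(corr, nfactors)
    if rotation == "auto":
        off = r - np.diag(np.diag(r))
        rotation = "promax" if np.abs(off).max() > 0.4 else "varimax"
    lam = fit.loadings.to_numpy()
    phi = np.eye(nfactors)
    if rotation == "promax" and nfactors >= 2:
        lam, phi = promax_rotate(lam, kappa)
    elif rotation == "varimax" and nfactors >= 2:
        lam, _ = varimax(lam)
        lam = _fix_signs(lam)
    elif rotation not in ("none", "promax", "varimax"):
        raise ValidationError(f"unknown rotation {rotation!r}")
    curve: dict = {}
    if vss_max:
        curve, _ = vss_curve(r, vss_max, complexity_c)
    frame = pd.DataFrame(
        lam, index=fit.loadings.index, columns=[f"F{j + 1}" for j in range(nfactors)]
    )
    return EFAResult(
        loadings=frame,
        phi=phi,
        uniquenesses=fit.uniquenesses,
        nfactors=nfactors,
        rotation=rotation,
        vss_curve=curve,
        converged=fit.converged,
    )


def factor_scores(data: pd.DataFrame, result: EFAResult, corr: np.ndarray | None = None) -> pd.DataFrame:
    """Regression-method factor scores for standardized data."""
    z = (data - data.mean()) / data.std(ddof=1)
    if corr is None:
        corr = np.corrcoef(z.to_numpy(), rowvar=False)
    lam = result.loadings.to_numpy()
    structure = lam @ result.phi
    weights = np.linalg.solve(corr, structure)
    scores = z.to_numpy() @ weights
    return pd.DataFrame(
        scores, index=data.index, columns=result.loadings.columns
    )
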