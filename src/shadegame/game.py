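"""Adaptive dynamics on performance matrices: PIPs and cESS detection.

The invasion exponent of a rare mutant strategy m in a resident population r
is log(mean mutant performance / mean resident performance); its sign map
over the strategy square is the pairwise invasibility plot (PIP).  To read
singular strategies off a noisy simulated matrix, the *performance* surface
w(m, r) is first interpolated with a two-dimensional penalized tensor-product
spline (generalized cross-validation picks the penalty), and the smoothed
invasion surface s(m, r) = log(w(m, r) / w(r, r)) — zero on the diagonal by
construction — is analysed: roots of the selection gradient
g(r) = ds/dm |_{m=r} are singular strategies, classified by the standard
second-order conditions (evolutionarily stable if d2s/dm2 < 0 at the point,
convergence stable if dg/dr < 0; both together give a cESS).
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .simulate import PerformanceMatrix

__all__ = [
    "InvasionMatrix",
    "SmoothedPIP",
    "SingularStrategy",
    "SingularSearch",
    "invasion_exponent",
    "invasion_ci",
    "smooth_performance",
    "find_singular_strategies",
    "classify_singular",
    "pip_export",
]


@dataclass
class InvasionMatrix:
    """Discrete invasion exponents with replicate confidence intervals."""

    strategies: np.ndarray
    exponents: np.ndarray          # (mutant, resident), diagonal exactly 0
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    includes_zero: np.ndarray      # bool, the "inconclusive" cells
    n_replicates: int
    undefined: np.ndarray          # bool, nonpositive mean performance

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mi, m in enumerate(self.strategies):
            for ri, r in enumerate(self.strategies):
                rows.append({
                    "mutant_alpha": m, "resident_alpha": r,
                    "invasion_exponent": self.exponents[mi, ri],
                    "ci_lo": self.ci_lo[mi, ri], "ci_hi": self.ci_hi[mi, ri],
                    "includes_zero": bool(self.includes_zero[mi, ri]),
                    "undefined": bool(self.undefined[mi, ri]),
                })
        return pd.DataFrame(rows)


def invasion_exponent(matrix: PerformanceMatrix) -> InvasionMatrix:
    """Discrete PIP: cell (m, r) = ln(mean w(m, r) / mean w(r, r)).

    The diagonal is forced to exactly zero; cells with a nonpositive mean
    are flagged undefined (NaN exponent).
    """
    mean = matrix.mean
    S = len(matrix.strategies)
    expo = np.full((S, S), np.nan)
    ci_lo = np.full((S, S), np.nan)
    ci_hi = np.full((S, S), np.nan)
    undefined = np.zeros((S, S), dtype=bool)
    n = matrix.n_replicates
    for ri in range(S):
        res_mean = mean[ri, ri]
        for mi in range(S):
            if mi == ri:
                expo[mi, ri] = 0.0
            elif mean[mi, ri] > 0 and res_mean > 0:
                expo[mi, ri] = math.log(mean[mi, ri] / res_mean)
            else:
                undefined[mi, ri] = True
            if n >= 2 and res_mean > 0:
                reps = matrix.replicates[mi, ri]
                reps = reps[np.isfinite(reps)]
                if len(reps) >= 2 and (reps > 0).all():
                    lo, hi, _ = invasion_ci(reps, res_mean, len(reps))
                    ci_lo[mi, ri], ci_hi[mi, ri] = lo, hi
    includes_zero = (ci_lo <= 0) & (ci_hi >= 0)
    return InvasionMatrix(matrix.strategies, expo, ci_lo, ci_hi,
                          includes_zero, n, undefined)


def invasion_ci(mutant_replicates, resident_mean: float, n: int):
    """CI of the invasion exponent: mean(x) +- sd(x)/sqrt(n-1) with
    x_i = ln(perf_i / resident mean).  Returns (lo, hi, includes_zero)."""
    if n < 2:
        raise ValueError("need n >= 2 replicates for a confidence interval")
    x = np.log(np.asarray(mutant_replicates, dtype=float) / resident_mean)
    half = x.std(ddof=1) / math.sqrt(n - 1)
    lo, hi = x.mean() - half, x.mean() + half
    return lo, hi, (lo <= 0 <= hi)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


#: default marginal basis size of the tensor smoother (as in mgcv's te());
#: capped at the grid size.  A stiff basis pools the whole matrix into the
#: gradient estimate, which the synthetic-landscape suite shows is what
#: limits recovery of the singular strategy under replicate noise.
DEFAULT_MARGINAL_BASIS = 5


def _basis(strategies: np.ndarray, degree: int = 3,
           n_basis: int | None = None):
    """Clamped cubic B-spline knots spanning the grid; basis size never
    exceeds the grid size."""
    x = np.asarray(strategies, dtype=float)
    if n_basis is None:
        n_basis = DEFAULT_MARGINAL_BASIS
    n_basis = max(degree + 1, min(n_basis, len(x)))
    n_interior = n_basis - degree - 1
    interior = (np.linspace(x[0], x[-1], n_interior + 2)[1:-1]
                if n_interior > 0 else np.array([]))
    knots = np.concatenate([[x[0]] * (degree + 1), interior,
                            [x[-1]] * (degree + 1)])
    return knots


def _design(x, knots, degree=3) -> np.ndarray:
    x = np.clip(np.atleast_1d(np.asarray(x, dtype=float)),
                knots[0], knots[-1])
    return BSpline.design_matrix(x, knots, degree).toarray()


@dataclass
class SmoothedPIP:
    """Penalized tensor-spline performance surface and its invasion geometry."""

    strategies: np.ndarray
    coef: np.ndarray               # (K, K) tensor coefficients, m by r
    knots: np.ndarray
    degree: int
    lam: float                     # chosen penalty
    edf: float                     # effective degrees of freedom
    gcv: float
    replicates: np.ndarray | None = None   # kept for bootstrap SEs

    @property
    def lo(self) -> float:
        return float(self.strategies[0])

    @property
    def hi(self) -> float:
        return float(self.strategies[-1])

    def performance(self, m, r) -> np.ndarray:
        """Smoothed w(m, r); m and r broadcast elementwise."""
        m = np.atleast_1d(m)
        r = np.atleast_1d(r)
        Bm = _design(m, self.knots, self.degree)
        Br = _design(r, self.knots, self.degree)
        return np.einsum("ik,kl,il->i", Bm, self.coef, Br)

    def surface(self, m, r) -> np.ndarray:
        """Smoothed invasion exponent s(m, r) = ln(w(m, r) / w(r, r))."""
        m, r = np.broadcast_arrays(np.atleast_1d(m), np.atleast_1d(r))
        w_m = self.performance(m.ravel(), r.ravel())
        w_r = self.performance(r.ravel(), r.ravel())
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.log(w_m / w_r)
        return out.reshape(m.shape)

    def gradient(self, r, step: float | None = None) -> np.ndarray:
        """Selection gradient g(r) = ds/dm at m = r (central difference)."""
        r = np.atleast_1d(np.asarray(r, dtype=float))
        h = step if step is not None else (self.hi - self.lo) / 200.0
        m_plus = np.minimum(r + h, self.hi)
        m_minus = np.maximum(r - h, self.lo)
        return ((self.surface(m_plus, r) - self.surface(m_minus, r))
                / (m_plus - m_minus))

    def isocline_points(self, mesh: int = 101) -> np.ndarray:
        """(m, r) points of the non-trivial s = 0 isocline."""
        rs = np.linspace(self.lo, self.hi, mesh)
        ms = np.linspace(self.lo, self.hi, mesh)
        pts = []
        tol = (self.hi - self.lo) / mesh
        for r in rs:
            vals = self.surface(ms, np.full_like(ms, r))
            for i in range(len(ms) - 1):
                a, b = vals[i], vals[i + 1]
                if not (np.isfinite(a) and np.isfinite(b)):
                    continue
                if a == 0.0 or a * b < 0:
                    m0 = ms[i] if a == 0 else ms[i] - a * (ms[i + 1] - ms[i]) / (b - a)
                    if abs(m0 - r) > tol:   # drop the identity line
                        pts.append((m0, r))
        return np.array(pts) if pts else np.zeros((0, 2))


def smooth_performance(matrix: PerformanceMatrix, degree: int = 3,
                       lambdas: np.ndarray | None = None,
                       n_basis: int | None = None) -> SmoothedPIP:
    """Fit the penalized tensor-product spline to mean performance.

    Smoothing acts on performance (not on exponents); the invasion surface is
    formed afterwards, so s(m, m) = 0 holds by construction.  The penalty is
    a second-order coefficient difference in each direction, whose null space
    contains every bilinear surface; lambda minimizes GCV.
    """
    S = len(matrix.strategies)
    if S < 4:
        raise ValueError("smoothing needs at least a 4x4 strategy grid")
    y = matrix.mean.ravel()   # m-major
    if not np.isfinite(y).all():
        raise ValueError("performance means contain NaN; fill failures first")
    knots = _basis(matrix.strategies, degree, n_basis)
    B = _design(matrix.strategies, knots, degree)   # (S, K)
    K = B.shape[1]
    X = np.kron(B, B)                               # (S*S, K*K)
    D = np.diff(np.eye(K), n=2, axis=0)
    P1 = D.T @ D
    pen = np.kron(P1, np.eye(K)) + np.kron(np.eye(K), P1)
    XtX = X.T @ X
    Xty = X.T @ y
    n = len(y)
    if lambdas is None:
        lambdas = np.logspace(-8, 4, 25)
    best = None
    for lam in lambdas:
        try:
            A = np.linalg.solve(XtX + lam * pen, np.column_stack([Xty, X.T]))
        except np.linalg.LinAlgError:
            continue
        beta, hat_core = A[:, 0], A[:, 1:]
        fitted = X @ beta
        edf = float(np.trace(X @ hat_core))
        denom = max(n - edf, 1e-8)
        gcv = n * float(((y - fitted) ** 2).sum()) / denom ** 2
        if best is None or gcv < best[0]:
            best = (gcv, lam, beta, edf)
    if best is None:
        raise np.linalg.LinAlgError("rank-deficient smoother fit at all lambdas")
    gcv, lam, beta, edf = best
    return SmoothedPIP(np.asarray(matrix.strategies, dtype=float),
                       beta.reshape(K, K), knots, degree,
                       float(lam), edf, gcv, matrix.replicates)


# ---------------------------------------------------------------------------
# singular strategies
# ---------------------------------------------------------------------------


@dataclass
class SingularStrategy:
    value: float
    classification: str            # cESS | ess_not_convergent | branching |
    #                                repeller | indeterminate
    ess_curvature: float = float("nan")      # d2s/dm2 at the point
    convergence_slope: float = float("nan")  # dg/dr at the point
    ess_se: float = float("nan")
    convergence_se: float = float("nan")
    uncertain: bool = False


@dataclass
class SingularSearch:
    """Roots of the selection gradient, or an out-of-range verdict."""

    roots: list[SingularStrategy]
    verdict: str   # "roots_found" | "beyond_range_high" | "beyond_range_low"
    #                | "degenerate"

    def __iter__(self):
        return iter(self.roots)

    def __len__(self):
        return len(self.roots)


def find_singular_strategies(pip: SmoothedPIP, mesh: int = 201,
                             tol: float = 1e-10) -> SingularSearch:
    """Locate roots of g(r) by sign-change bracketing plus bisection.

    When g keeps one sign over the whole tested range, the singular strategy
    lies beyond the tested values: the verdict says in which direction
    selection points.  No extrapolation is attempted.
    """
    rs = np.linspace(pip.lo, pip.hi, mesh)
    g = pip.gradient(rs)
    if np.nanmax(np.abs(g)) < tol:
        return SingularSearch([], "degenerate")
    roots = []
    for i in range(mesh - 1):
        a, b = g[i], g[i + 1]
        if not (np.isfinite(a) and np.isfinite(b)):
            continue
        if a == 0.0:
            roots.append(rs[i])
        elif a * b < 0:
            lo, hi = rs[i], rs[i + 1]
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                gm = float(pip.gradient(mid)[0])
                if gm == 0.0:
                    break
                if gm * a < 0:
                    hi = mid
                else:
                    lo = mid
            roots.append(0.5 * (lo + hi))
    if g[-1] == 0.0:
        roots.append(rs[-1])
    if not roots:
        verdict = ("beyond_range_high" if np.nanmean(g) > 0
                   else "beyond_range_low")
        return SingularSearch([], verdict)
    out = [SingularStrategy(float(r), "unclassified") for r in roots]
    return SingularSearch(out, "roots_found")


def _second_derivatives(pip: SmoothedPIP, a: float, h: float):
    """(d2s/dm2, dg/dr) at the singular point by finite differences."""
    e2 = float((pip.surface(a + h, a) - 2.0 * pip.surface(a, a)
                + pip.surface(a - h, a))[0]) / h ** 2
    dg = float((pip.gradient(a + h) - pip.gradient(a - h))[0]) / (2.0 * h)
    return e2, dg


def classify_singular(pip: SmoothedPIP, alpha_star: float,
                      step: float | None = None,
                      n_bootstrap: int = 40,
                      rng: np.random.Generator | None = None) -> SingularStrategy:
    """Second-order classification of a singular strategy.

    ESS: d2s/dm2 < 0 at (a*, a*); convergence: dg/dr < 0; cESS needs both.
    Derivatives use finite differences with step = range/200.  When replicate
    data are attached, a bootstrap over replicates (refitting with the chosen
    penalty) supplies standard errors; a derivative within 2 SE of zero makes
    the verdict "indeterminate".  Points on the range boundary are refused.
    """
    h = step if step is not None else (pip.hi - pip.lo) / 200.0
    if alpha_star <= pip.lo + h or alpha_star >= pip.hi - h:
        raise ValueError(f"singular strategy {alpha_star} too close to the "
                         "tested range boundary; classification refused")
    e2, dg = _second_derivatives(pip, alpha_star, h)
    se_e2 = se_dg = float("nan")
    if pip.replicates is not None and np.isfinite(pip.replicates).all() \
            and pip.replicates.shape[2] >= 2:
        rng = rng or np.random.default_rng(0)
        K = pip.replicates.shape[2]
        boots_e2, boots_dg = [], []
        for _ in range(n_bootstrap):
            pick = rng.integers(0, K, size=K)
            bmat = PerformanceMatrix(0.0, 0.0, pip.strategies,
                                     pip.replicates[:, :, pick])
            try:
                bpip = smooth_performance(bmat, pip.degree,
                                          lambdas=np.array([pip.lam]))
                b_e2, b_dg = _second_derivatives(bpip, alpha_star, h)
                boots_e2.append(b_e2)
                boots_dg.append(b_dg)
            except (np.linalg.LinAlgError, ValueError):
                continue
        if len(boots_e2) >= 10:
            se_e2 = float(np.std(boots_e2, ddof=1))
            se_dg = float(np.std(boots_dg, ddof=1))
    ess = e2 < 0
    convergent = dg < 0
    uncertain = False
    if np.isfinite(se_e2) and (abs(e2) < 2 * se_e2 or abs(dg) < 2 * se_dg):
        label = "indeterminate"
        uncertain = True
    elif ess and convergent:
        label = "cESS"
    elif ess:
        label = "ess_not_convergent"
    elif convergent:
        label = "branching"
    else:
        label = "repeller"
    return SingularStrategy(float(alpha_star), label, e2, dg,
                            se_e2, se_dg, uncertain)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def pip_export(discrete: InvasionMatrix, smoothed: SmoothedPIP | None,
               outdir: str, prefix: str = "pip",
               surface_mesh: int = 81, make_plot: bool = True) -> dict:
    """Write discrete-cell and smoothed-surface CSVs plus a two-panel figure
    (diverging red-blue about zero, identity line drawn)."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    disc = discrete.to_frame()
    paths["discrete"] = os.path.join(outdir, f"{prefix}_discrete.csv")
    disc.to_csv(paths["discrete"], index=False)
    if smoothed is not None:
        mesh = np.linspace(smoothed.lo, smoothed.hi, surface_mesh)
        M, R = np.meshgrid(mesh, mesh, indexing="ij")
        S = smoothed.surface(M, R)
        surf = pd.DataFrame({"mutant_alpha": M.ravel(),
                             "resident_alpha": R.ravel(),
                             "invasion_exponent": S.ravel()})
        paths["smoothed"] = os.path.join(outdir, f"{prefix}_smoothed.csv")
        surf.to_csv(paths["smoothed"], index=False)
    if make_plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ncol = 2 if smoothed is not None else 1
        fig, axes = plt.subplots(1, ncol, figsize=(5 * ncol, 4.2),
                                 squeeze=False)
        ax = axes[0, 0]
        lim = np.nanmax(np.abs(discrete.exponents)) or 1.0
        ax.pcolormesh(discrete.strategies, discrete.strategies,
                      discrete.exponents.T, cmap="RdBu", vmin=-lim, vmax=lim,
                      shading="nearest")
        ax.plot(discrete.strategies, discrete.strategies, "k-", lw=1)
        ax.set_xlabel("mutant strategy")
        ax.set_ylabel("resident strategy")
        ax.set_title("discrete PIP")
        if smoothed is not None:
            ax = axes[0, 1]
            lim = np.nanmax(np.abs(S)) or 1.0
            ax.pcolormesh(mesh, mesh, S.T, cmap="RdBu", vmin=-lim, vmax=lim,
                          shading="nearest")
            ax.plot(mesh, mesh, "k-", lw=1)
            iso = smoothed.isocline_points()
            if len(iso):
                ax.plot(iso[:, 0], iso[:, 1], "k.", ms=2)
            ax.set_xlabel("mutant strategy")
            ax.set_title("smoothed PIP")
        fig.tight_layout()
        paths["figure"] = os.path.join(outdir, f"{prefix}.png")
        fig.savefig(paths["figure"], dpi=120)
        plt.close(fig)
    return paths
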