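"""GRM-based REML for variance components: the verification path.

The model is the genomic animal model

    y = mu + herd + parity + a + e,   a ~ N(0, G sa2),  e ~ N(0, I se2),

where G is the genomic relationship matrix. Univariate fits give
h2 = sa2 / (sa2 + se2); bivariate fits estimate 2x2 genomic and residual
covariance matrices and hence the genomic correlation.

Estimation is average-information (AI) REML with EM fallback: the first
iterations and any AI proposal that leaves the parameter space (negative
variance, |correlation| > 1) are replaced by an EM update, which cannot
decrease the restricted likelihood. Weakly identified data sets drive
the genomic correlation to the +-1 boundary; such fits are flagged
(``boundary_flag``) rather than hidden, because a correlation pinned at
the boundary signals a convergence problem, not a trustworthy estimate.

Standard errors come from the inverse of the final AI matrix, with the
delta method for h2 and the correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .grm import GRM

logger = logging.getLogger(__name__)

__all__ = ["REMLOptions", "REMLResult", "reml_univariate", "reml_bivariate", "compare_bayes_reml"]


@dataclass
class REMLOptions:
    max_iterations: int = 100
    tol_param: float = 1e-8     # relative parameter change
    tol_grad: float = 1e-6      # scaled gradient norm
    ridge: float = 1e-6         # added to G's diagonal before factorisation
    max_correlation: float = 0.999  # |r| beyond this is a boundary estimate
    n_em_start: int = 3         # EM warm-up iterations before switching to AI
    variance_floor_factor: float = 1e-8  # x phenotypic variance


@dataclass
class REMLResult:
    trait_names: list[str]
    sigma_a2: np.ndarray        # per trait
    sigma_e2: np.ndarray
    cov_a: float | None         # bivariate genomic covariance
    cov_e: float | None
    h2: np.ndarray
    h2_se: np.ndarray
    genomic_correlation: float | None
    genomic_correlation_se: float | None
    environmental_correlation: float | None
    converged: bool
    boundary_flag: bool
    n_iterations_used: int
    loglik: float
    ai_matrix: np.ndarray = field(repr=False, default=None)
    loglik_trace: list = field(repr=False, default_factory=list)

    def to_dict(self) -> dict:
        return {
            "trait_names": self.trait_names,
            "sigma_a2": self.sigma_a2.tolist(),
            "sigma_e2": self.sigma_e2.tolist(),
            "cov_a": self.cov_a,
            "cov_e": self.cov_e,
            "h2": self.h2.tolist(),
            "h2_se": self.h2_se.tolist(),
            "genomic_correlation": self.genomic_correlation,
            "genomic_correlation_se": self.genomic_correlation_se,
            "environmental_correlation": self.environmental_correlation,
            "converged": self.converged,
            "boundary_flag": self.boundary_flag,
            "n_iterations_used": self.n_iterations_used,
            "loglik": self.loglik,
        }


def _fixed_design(herd: np.ndarray, parity: np.ndarray) -> np.ndarray:
    """Intercept + reference-coded herd and parity incidence (full rank)."""
    n = len(herd)
    cols = [np.ones(n)]
    for factor in (np.asarray(herd).astype(str), np.asarray(parity).astype(str)):
        for lev in sorted(set(factor))[1:]:
            cols.append((factor == lev).astype(float))
    return np.column_stack(cols)


def _p_matrix(V: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """REML projection matrix P and the two log-determinant terms."""
    c = cho_factor(V, lower=True)
    logdet_v = 2.0 * np.sum(np.log(np.diag(c[0])))
    Vi = cho_solve(c, np.eye(V.shape[0]))
    ViX = Vi @ X
    XtViX = X.T @ ViX
    cx = cho_factor(XtViX, lower=True)
    logdet_x = 2.0 * np.sum(np.log(np.diag(cx[0])))
    P = Vi - ViX @ cho_solve(cx, ViX.T)
    return P, logdet_v + logdet_x


def reml_univariate(
    y: np.ndarray,
    herd: np.ndarray,
    parity: np.ndarray,
    G: GRM,
    options: REMLOptions | None = None,
) -> REMLResult:
    """Univariate AI-REML with a genomic relationship matrix.

    Raises if G carries no relationship information (G = I makes the
    split between sa2 and se2 unidentifiable).
    """
    opt = options or REMLOptions()
    y = np.asarray(y, dtype=float)
    n = y.size
    if G.n != n:
        raise ValueError("GRM order does not match the number of phenotypes")
    Gm = G.values + opt.ridge * np.eye(n)
    if opt.ridge > 0:
        logger.debug("ridge %g added to the GRM diagonal", opt.ridge)
    if np.linalg.norm(G.values - np.eye(n)) / np.sqrt(n) < 1e-8:
        raise ValueError("G is (numerically) the identity: sa2 and se2 are not separable")
    ev_min = float(np.linalg.eigvalsh(Gm).min())
    if ev_min < -1e-6:
        raise ValueError(f"GRM is not positive semi-definite (min eigenvalue {ev_min:.3g})")

    X = _fixed_design(herd, parity)
    vary = float(np.var(y, ddof=1))
    floor = opt.variance_floor_factor * vary
    theta = np.array([0.5 * vary, 0.5 * vary])  # (sa2, se2)
    I_n = np.eye(n)
    loglik = -np.inf
    converged = False
    it = 0
    AI = np.eye(2)
    trace: list[float] = []
    for it in range(1, opt.max_iterations + 1):
        V = theta[0] * Gm + theta[1] * I_n
        P, logdets = _p_matrix(V, X)
        t = P @ y
        new_loglik = -0.5 * (logdets + float(y @ t))
        trace.append(new_loglik)
        Gt = Gm @ t
        # score and AI on (sa2, se2)
        trPG = float(np.sum(P * Gm))
        trP = float(np.trace(P))
        score = -0.5 * np.array([trPG - float(t @ Gt), trP - float(t @ t)])
        s_a, s_e = Gt, t
        Ps_a, Ps_e = P @ s_a, P @ s_e
        AI = 0.5 * np.array(
            [[s_a @ Ps_a, s_a @ Ps_e], [s_e @ Ps_a, s_e @ Ps_e]]
        )
        grad_norm = float(np.linalg.norm(score)) / max(vary, 1e-12)

        use_em = it <= opt.n_em_start
        if not use_em:
            try:
                delta = np.linalg.solve(AI, score)
            except np.linalg.LinAlgError:
                use_em = True
            else:
                proposal = theta + delta
                if np.any(proposal < floor):
                    use_em = True
        if use_em:
            # EM increments: theta_k + theta_k^2/n * (t'V_k t - tr(P V_k))
            proposal = np.array(
                [
                    theta[0] + theta[0] ** 2 / n * (float(t @ Gt) - trPG),
                    theta[1] + theta[1] ** 2 / n * (float(t @ t) - trP),
                ]
            )
        proposal = np.maximum(proposal, floor)
        rel_change = float(np.max(np.abs(proposal - theta) / np.maximum(theta, 1e-12)))
        theta = proposal
        if rel_change < opt.tol_param and grad_norm < opt.tol_grad:
            converged = True
            loglik = new_loglik
            break
        loglik = new_loglik
    boundary = bool(np.any(theta <= floor * (1.0 + 1e-6)))
    if not converged:
        logger.warning("univariate REML did not converge in %d iterations", it)

    sa2, se2 = theta
    h2 = sa2 / (sa2 + se2)
    try:
        C = np.linalg.inv(AI)
        grad = np.array([se2, -sa2]) / (sa2 + se2) ** 2
        h2_se = float(np.sqrt(max(grad @ C @ grad, 0.0)))
    except np.linalg.LinAlgError:
        h2_se = np.nan
    return REMLResult(
        trait_names=["trait"],
        sigma_a2=np.array([sa2]),
        sigma_e2=np.array([se2]),
        cov_a=None,
        cov_e=None,
        h2=np.array([h2]),
        h2_se=np.array([h2_se]),
        genomic_correlation=None,
        genomic_correlation_se=None,
        environmental_correlation=None,
        converged=converged,
        boundary_flag=boundary,
        n_iterations_used=it,
        loglik=loglik,
        ai_matrix=AI,
        loglik_trace=trace,
    )


def _clamp_cov(S: np.ndarray, floor: np.ndarray, max_corr: float) -> tuple[np.ndarray, bool]:
    """Force diagonals above their floors and |correlation| <= max_corr."""
    S = S.copy()
    hit = False
    for t in range(2):
        if S[t, t] < floor[t]:
            S[t, t] = floor[t]
            hit = True
    lim = max_corr * np.sqrt(S[0, 0] * S[1, 1])
    if abs(S[0, 1]) > lim:
        S[0, 1] = S[1, 0] = np.sign(S[0, 1]) * lim
        hit = True
    return S, hit


def reml_bivariate(
    y1: np.ndarray,
    y2: np.ndarray,
    herd: np.ndarray,
    parity: np.ndarray,
    G: GRM,
    options: REMLOptions | None = None,
) -> REMLResult:
    """Bivariate AI-REML: 2x2 genomic and residual covariance matrices.

    Parameters are ordered (g11, g12, g22, e11, e12, e22). A fit whose
    genomic correlation sits at the +-``max_correlation`` boundary (or a
    variance at its floor) is returned with ``boundary_flag`` set.
    """
    opt = options or REMLOptions()
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    n = y1.size
    if y2.size != n:
        raise ValueError("both traits must be observed on the same individuals")
    if G.n != n:
        raise ValueError("GRM order does not match the number of phenotypes")
    Gm = G.values + opt.ridge * np.eye(n)

    Xs = _fixed_design(herd, parity)
    X = np.kron(np.eye(2), Xs)
    y = np.concatenate([y1, y2])
    v1, v2 = float(np.var(y1, ddof=1)), float(np.var(y2, ddof=1))
    floor = opt.variance_floor_factor * np.array([v1, v2])
    Sg = np.diag([0.5 * v1, 0.5 * v2])
    Se = np.diag([0.5 * v1, 0.5 * v2])
    I_n = np.eye(n)

    def build_v(Sg: np.ndarray, Se: np.ndarray) -> np.ndarray:
        return np.kron(Sg, Gm) + np.kron(Se, I_n)

    converged = False
    loglik = -np.inf
    clamped = False
    AI = np.eye(6)
    it = 0
    trace: list[float] = []
    for it in range(1, opt.max_iterations + 1):
        V = build_v(Sg, Se)
        try:
            P, logdets = _p_matrix(V, X)
        except np.linalg.LinAlgError:
            # covariance proposal too extreme: shrink the correlations
            Sg[0, 1] = Sg[1, 0] = 0.9 * Sg[0, 1]
            Se[0, 1] = Se[1, 0] = 0.9 * Se[0, 1]
            clamped = True
            continue
        t = P @ y
        new_loglik = -0.5 * (logdets + float(y @ t))
        trace.append(new_loglik)
        t1, t2 = t[:n], t[n:]
        Gt1, Gt2 = Gm @ t1, Gm @ t2
        # block traces T[s,s'] = tr(P_ss' G) and tr(P_ss')
        P11, P12, P22 = P[:n, :n], P[:n, n:], P[n:, n:]
        Tg = np.array(
            [[np.sum(P11 * Gm), np.sum(P12 * Gm)], [np.sum(P12 * Gm), np.sum(P22 * Gm)]]
        )
        Te = np.array(
            [[np.trace(P11), np.trace(P12)], [np.trace(P12), np.trace(P22)]]
        )
        Qg = np.array([[t1 @ Gt1, t1 @ Gt2], [t1 @ Gt2, t2 @ Gt2]])
        Qe = np.array([[t1 @ t1, t1 @ t2], [t1 @ t2, t2 @ t2]])

        # score for (g11, g12, g22, e11, e12, e22)
        score = -0.5 * np.array(
            [
                Tg[0, 0] - Qg[0, 0],
                2.0 * (Tg[0, 1] - Qg[0, 1]),
                Tg[1, 1] - Qg[1, 1],
                Te[0, 0] - Qe[0, 0],
                2.0 * (Te[0, 1] - Qe[0, 1]),
                Te[1, 1] - Qe[1, 1],
            ]
        )
        # AI matrix: s_k = dV/dtheta_k @ t
        s_list = [
            np.concatenate([Gt1, np.zeros(n)]),
            np.concatenate([Gt2, Gt1]),
            np.concatenate([np.zeros(n), Gt2]),
            np.concatenate([t1, np.zeros(n)]),
            np.concatenate([t2, t1]),
            np.concatenate([np.zeros(n), t2]),
        ]
        S_mat = np.column_stack(s_list)
        AI = 0.5 * (S_mat.T @ (P @ S_mat))
        grad_norm = float(np.linalg.norm(score)) / max(v1, v2)

        theta = np.array([Sg[0, 0], Sg[0, 1], Sg[1, 1], Se[0, 0], Se[0, 1], Se[1, 1]])
        use_em = it <= opt.n_em_start
        proposal = None
        if not use_em:
            try:
                delta = np.linalg.solve(AI + 1e-10 * np.eye(6), score)
                proposal = theta + delta
            except np.linalg.LinAlgError:
                use_em = True
            else:
                Sg_p = np.array([[proposal[0], proposal[1]], [proposal[1], proposal[2]]])
                Se_p = np.array([[proposal[3], proposal[4]], [proposal[4], proposal[5]]])
                if (
                    Sg_p[0, 0] < floor[0] or Sg_p[1, 1] < floor[1]
                    or Se_p[0, 0] < floor[0] or Se_p[1, 1] < floor[1]
                ):
                    use_em = True
        if use_em:
            # EM increments: S_new = S + (1/n) S (Q - T) S, separately for
            # the genomic and residual covariance matrices
            Sg_p = Sg + (Sg @ (Qg - Tg) @ Sg) / n
            Se_p = Se + (Se @ (Qe - Te) @ Se) / n
        Sg_p, hit_g = _clamp_cov(Sg_p, floor, opt.max_correlation)
        Se_p, hit_e = _clamp_cov(Se_p, floor, opt.max_correlation)
        hit_now = hit_g or hit_e
        clamped = clamped or hit_now
        new_theta = np.array([Sg_p[0, 0], Sg_p[0, 1], Sg_p[1, 1], Se_p[0, 0], Se_p[0, 1], Se_p[1, 1]])
        rel_change = float(
            np.max(np.abs(new_theta - theta) / np.maximum(np.abs(theta), 1e-12))
        )
        Sg, Se = Sg_p, Se_p
        # at an interior optimum both conditions must hold; when the update
        # is being actively clamped to the boundary the gradient never
        # vanishes, so parameter stability alone ends the iteration
        if rel_change < opt.tol_param and (grad_norm < opt.tol_grad or hit_now):
            converged = True
            loglik = new_loglik
            break
        loglik = new_loglik
    if not converged:
        logger.warning("bivariate REML did not converge in %d iterations", it)

    r_g = float(Sg[0, 1] / np.sqrt(Sg[0, 0] * Sg[1, 1]))
    r_e = float(Se[0, 1] / np.sqrt(Se[0, 0] * Se[1, 1]))
    h2 = np.array([Sg[0, 0] / (Sg[0, 0] + Se[0, 0]), Sg[1, 1] / (Sg[1, 1] + Se[1, 1])])
    boundary = bool(
        abs(r_g) >= opt.max_correlation - 1e-9
        or Sg[0, 0] <= floor[0] * (1 + 1e-6)
        or Sg[1, 1] <= floor[1] * (1 + 1e-6)
    )
    try:
        C = np.linalg.inv(AI + 1e-10 * np.eye(6))
        g11, g12, g22 = Sg[0, 0], Sg[0, 1], Sg[1, 1]
        grad_r = np.array(
            [-r_g / (2 * g11), 1.0 / np.sqrt(g11 * g22), -r_g / (2 * g22), 0.0, 0.0, 0.0]
        )
        r_se = float(np.sqrt(max(grad_r @ C @ grad_r, 0.0)))
        h2_se = np.empty(2)
        for tix, (gv, ev, gslot, eslot) in enumerate(
            [(g11, Se[0, 0], 0, 3), (g22, Se[1, 1], 2, 5)]
        ):
            grad_h = np.zeros(6)
            grad_h[gslot] = ev / (gv + ev) ** 2
            grad_h[eslot] = -gv / (gv + ev) ** 2
            h2_se[tix] = np.sqrt(max(grad_h @ C @ grad_h, 0.0))
    except np.linalg.LinAlgError:
        r_se = np.nan
        h2_se = np.full(2, np.nan)
    return REMLResult(
        trait_names=["trait1", "trait2"],
        sigma_a2=np.array([Sg[0, 0], Sg[1, 1]]),
        sigma_e2=np.array([Se[0, 0], Se[1, 1]]),
        cov_a=float(Sg[0, 1]),
        cov_e=float(Se[0, 1]),
        h2=h2,
        h2_se=h2_se,
        genomic_correlation=r_g,
        genomic_correlation_se=r_se,
        environmental_correlation=r_e,
        converged=converged,
        boundary_flag=boundary,
        n_iterations_used=it,
        loglik=loglik,
        ai_matrix=AI,
        loglik_trace=trace,
    )


def compare_bayes_reml(
    bayes: list,
    reml: list[REMLResult],
    pair_names: list[tuple[str, str]] | None = None,
    phenotypic: list[float] | None = None,
) -> pd.DataFrame:
    """Paired genomic-correlation table for the two estimation routes.

    One row per trait pair with both estimates, their absolute
    difference, the REML boundary flag and (optionally) the raw
    phenotypic correlation. The ``agreement`` attribute on the returned
    frame holds the mean |Bayes - REML| over non-boundary REML fits only,
    since a boundary estimate is a convergence failure, not a value.
    """
    if len(bayes) != len(reml):
        raise ValueError("need one REML result per Bayesian posterior")
    if pair_names is None:
        pair_names = [("trait1", "trait2")] * len(bayes)
    rows = []
    for k, (b, r) in enumerate(zip(bayes, reml)):
        rows.append(
            {
                "trait1": pair_names[k][0],
                "trait2": pair_names[k][1],
                "r_bayes": b.genomic_correlation_mean,
                "r_bayes_psd": b.genomic_correlation_psd,
                "r_reml": r.genomic_correlation,
                "r_reml_se": r.genomic_correlation_se,
                "abs_difference": abs(b.genomic_correlation_mean - r.genomic_correlation),
                "reml_boundary": r.boundary_flag,
                "phenotypic_correlation": phenotypic[k] if phenotypic is not None else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    ok = ~table["reml_boundary"]
    table.attrs["agreement"] = float(table.loc[ok, "abs_difference"].mean()) if ok.any() else np.nan
    table.attrs["n_boundary"] = int(table["reml_boundary"].sum())
    return table


def plot_method_comparison(table: pd.DataFrame, path: str) -> None:
    """Scatter of Bayesian vs REML genomic correlations (boundary fits
    highlighted), the standard visual check of the two routes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ok = ~table["reml_boundary"]
    ax.scatter(table.loc[ok, "r_bayes"], table.loc[ok, "r_reml"], c="tab:blue", label="converged")
    ax.scatter(
        table.loc[~ok, "r_bayes"], table.loc[~ok, "r_reml"],
        c="tab:red", marker="D", label="REML boundary",
    )
    ax.plot([-1, 1], [-1, 1], "k--", lw=0.8)
    ax.set_xlabel("genomic correlation (Bayesian)")
    ax.set_ylabel("genomic correlation (REML)")
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_phenotypic_vs_genomic(table: pd.DataFrame, path: str) -> None:
    """Raw phenotypic correlation against the genomic correlation from
    both methods."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(table["phenotypic_correlation"], table["r_bayes"], c="tab:blue", label="Bayesian")
    ax.scatter(
        table["phenotypic_correlation"], table["r_reml"], c="tab:red", marker="D", label="REML"
    )
    ax.set_xlabel("raw phenotypic correlation")
    ax.set_ylabel("genomic correlation")
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
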