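"""Bayesian random-regression SNP-BLUP samplers (univariate and bivariate).

The model is the additive SNP-regression mixed model

    y = mu + X1 b1 + X2 b2 + Z u + e,
    u ~ N(0, I su2),  e ~ N(0, I se2),

with herd and parity as fixed cross-classified effects, flat priors on
the fixed effects, and flat (uniform, optionally right-truncated) priors
on the variances. Posterior sampling is single-site Gibbs: fixed effects
and every SNP effect from their normal full conditionals, se2 and su2
from scaled inverse-chi-square full conditionals with n-2 and m-2
degrees of freedom. An optional Metropolis-Hastings mode replaces the
exact Gibbs draw of each SNP effect with a random-walk proposal whose
step size adapts during burn-in; variances are still Gibbs-updated, and
the Gibbs sampler is the correctness reference for this mode.

In the bivariate model each SNP carries a 2-vector of effects with an
unknown 2x2 covariance Su, residual 2-vectors have covariance Se, and
both matrices get inverse-Wishart full conditionals (flat matrix priors,
degrees of freedom m-3 and n-3).

The quantities of scientific interest are computed per saved cycle from
the current state: the SNP-explained (genomic) variance sa2 = Var(Zu)
using the population (n-denominator) variance over individuals, the
heritability h2 = sa2 / (sa2 + se2), and - bivariately - the genomic
correlation r = Cov(Zu1, Zu2) / sqrt(Var(Zu1) Var(Zu2)) and the residual
correlation from the Se draws. Posterior summaries are the mean and the
sample (n-1 denominator) standard deviation of those derived draws.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .qc import CenteredDesign

logger = logging.getLogger(__name__)

__all__ = [
    "ModelFrame",
    "MCMCConfig",
    "ChainResult",
    "PosteriorSummary",
    "BivariatePosterior",
    "build_model_frame",
    "run_univariate_chain",
    "run_bivariate_chain",
    "genomic_variance",
    "summarize_chain",
]


# ----------------------------------------------------------------------
# model frame


@dataclass
class ModelFrame:
    """Aligned response, fixed-effect design and SNP covariates.

    ``W`` holds the intercept plus herd and parity incidence with the
    first level of each factor absorbed into the intercept (reference
    coding), which keeps the fixed-effect design full rank.
    """

    y: np.ndarray            # n (univariate) or n x 2
    W: np.ndarray            # n x p fixed design, first column = intercept
    Z: np.ndarray            # n x m centered SNP covariates
    trait_names: list[str]
    fixed_names: list[str]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        n = self.Z.shape[0]
        if self.W.shape[0] != n or self.y.shape[0] != n:
            raise ValueError("row counts of y, W and Z disagree")
        if np.isnan(self.y).any():
            raise ValueError("missing phenotypes must be dropped before sampling")

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def m(self) -> int:
        return self.Z.shape[1]

    @property
    def n_traits(self) -> int:
        return 1 if self.y.ndim == 1 else self.y.shape[1]


def build_model_frame(
    pheno: pd.DataFrame,
    traits: str | list[str],
    design: CenteredDesign,
) -> ModelFrame:
    """Align phenotypes with the centered genotype design and build the
    fixed-effect incidence. Rows with any requested trait missing are
    dropped (and the count logged)."""
    trait_list = [traits] if isinstance(traits, str) else list(traits)
    if not 1 <= len(trait_list) <= 2:
        raise ValueError("one or two traits per model frame")
    df = pheno.set_index("id").loc[list(design.individual_ids)].reset_index()
    ok = df[trait_list].notna().all(axis=1).to_numpy()
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropping %d individual(s) with missing phenotype(s)", n_dropped)
    if ok.sum() < 2:
        raise ValueError("fewer than two individuals with complete phenotypes")
    df = df.loc[ok]
    Z = design.Z[ok]

    cols = [np.ones(len(df))]
    names = ["intercept"]
    for factor in ("herd", "parity"):
        levels = sorted(df[factor].astype(str).unique())
        for lev in levels[1:]:  # first level absorbed into the intercept
            cols.append((df[factor].astype(str) == lev).to_numpy(float))
            names.append(f"{factor}:{lev}")
    W = np.column_stack(cols)
    y = df[trait_list].to_numpy(float)
    if len(trait_list) == 1:
        y = y[:, 0]
    return ModelFrame(y=y, W=W, Z=Z, trait_names=trait_list, fixed_names=names, n_dropped=n_dropped)


# ----------------------------------------------------------------------
# configuration and results


@dataclass
class MCMCConfig:
    n_iterations: int = 100_000
    burn_in: int = 10_000
    thin: int = 100
    seed: int = 0
    sampler: str = "gibbs"   # "gibbs" | "metropolis_hastings"
    variance_upper_bound: float | None = None
    var_zu_denominator: str = "n"  # "n" (population) or "n-1" (sample)

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.sampler not in ("gibbs", "metropolis_hastings"):
            raise ValueError(f"unknown sampler {self.sampler!r}")
        if self.var_zu_denominator not in ("n", "n-1"):
            raise ValueError("var_zu_denominator must be 'n' or 'n-1'")

    @property
    def n_saved(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass
class ChainResult:
    """Thinned posterior draws plus derived per-cycle quantities."""

    trait_names: list[str]
    sigma_u2: np.ndarray       # S (univariate) or S x 3 (su11, su12, su22)
    sigma_e2: np.ndarray       # S or S x 3 (se11, se12, se22)
    var_zu: np.ndarray         # S or S x 2
    cov_zu: np.ndarray | None  # S (bivariate only)
    h2: np.ndarray             # S or S x 2
    r_genomic: np.ndarray | None
    r_environmental: np.ndarray | None
    fixed_effects: np.ndarray  # S x p (univariate) or S x p x 2
    u_posterior_mean: np.ndarray
    acceptance_rate: float | None = None
    runtime_seconds: float = 0.0
    seed: int = 0

    @property
    def n_saved(self) -> int:
        return self.var_zu.shape[0]

    def to_tsv(self, path: str) -> None:
        cols: dict[str, np.ndarray] = {}
        if len(self.trait_names) == 1:
            cols["sigma_u2"] = self.sigma_u2
            cols["sigma_e2"] = self.sigma_e2
            cols["var_zu"] = self.var_zu
            cols["h2"] = self.h2
        else:
            for k, lab in enumerate(("11", "12", "22")):
                cols[f"sigma_u2_{lab}"] = self.sigma_u2[:, k]
                cols[f"sigma_e2_{lab}"] = self.sigma_e2[:, k]
            for t in range(2):
                cols[f"var_zu_{t + 1}"] = self.var_zu[:, t]
                cols[f"h2_{t + 1}"] = self.h2[:, t]
            cols["cov_zu"] = self.cov_zu
            cols["r_genomic"] = self.r_genomic
            cols["r_environmental"] = self.r_environmental
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


@dataclass
class PosteriorSummary:
    trait: str
    h2_mean: float
    h2_psd: float
    var_zu_mean: float
    var_zu_psd: float
    sigma_e2_mean: float
    sigma_e2_psd: float
    ess: float = np.nan
    geweke_z: float = np.nan

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2_mean <= 1.0:
            raise ValueError("posterior mean heritability outside [0, 1]")


@dataclass
class BivariatePosterior:
    genomic_correlation_mean: float
    genomic_correlation_psd: float
    environmental_correlation_mean: float
    environmental_correlation_psd: float
    traits: list[PosteriorSummary] = field(default_factory=list)

    def __post_init__(self) -> None:
        for v in (self.genomic_correlation_mean, self.environmental_correlation_mean):
            if not -1.0 <= v <= 1.0:
                raise ValueError("correlation posterior mean outside [-1, 1]")


# ----------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _kernel_univariate(y, W, Z, n_iter, burn, thin, seed, su2, se2,
                       update_vars, var_upper, use_mh, pop_var):
    np.random.seed(seed)
    n, m = Z.shape
    p = W.shape[1]
    wtw = np.empty(p)
    for k in range(p):
        s = 0.0
        for i in range(n):
            s += W[i, k] * W[i, k]
        wtw[k] = s
    ztz = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Z[i, j] * Z[i, j]
        ztz[j] = s

    beta = np.zeros(p)
    u = np.zeros(m)
    e = y.copy()

    n_saved = (n_iter - burn) // thin
    su2_s = np.empty(n_saved)
    se2_s = np.empty(n_saved)
    varzu_s = np.empty(n_saved)
    beta_s = np.empty((n_saved, p))
    u_mean = np.zeros(m)

    step = 0.1 * np.sqrt(su2)
    acc_win = 0
    prop_win = 0
    acc_post = 0
    prop_post = 0
    isave = 0

    for it in range(1, n_iter + 1):
        # fixed effects: single-site normal full conditionals, flat prior
        for k in range(p):
            bk = beta[k]
            rhs = 0.0
            for i in range(n):
                rhs += W[i, k] * e[i]
            rhs += wtw[k] * bk
            mean = rhs / wtw[k]
            newb = mean + np.random.normal() * np.sqrt(se2 / wtw[k])
            diff = bk - newb
            for i in range(n):
                e[i] += W[i, k] * diff
            beta[k] = newb

        # SNP effects
        lam = se2 / su2 if su2 > 0.0 else 1e300
        for j in range(m):
            uj = u[j]
            rhs = 0.0
            for i in range(n):
                rhs += Z[i, j] * e[i]
            rhs += ztz[j] * uj
            c = ztz[j] + lam
            mean = rhs / c
            var = se2 / c
            if use_mh:
                prop = uj + step * np.random.normal()
                logr = -0.5 * ((prop - mean) ** 2 - (uj - mean) ** 2) / var
                if it <= burn:
                    prop_win += 1
                else:
                    prop_post += 1
                if np.log(np.random.random()) < logr:
                    if it <= burn:
                        acc_win += 1
                    else:
                        acc_post += 1
                    newu = prop
                else:
                    newu = uj
            else:
                newu = mean + np.random.normal() * np.sqrt(var)
            diff = uj - newu
            for i in range(n):
                e[i] += Z[i, j] * diff
            u[j] = newu

        # adapt the MH step toward ~40% acceptance during burn-in
        if use_mh and it <= burn and prop_win >= 50 * m:
            rate = acc_win / prop_win
            step *= np.exp(rate - 0.4)
            acc_win = 0
            prop_win = 0

        # variances: scaled inverse-chi-square full conditionals (flat prior)
        if update_vars:
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            se2 = sse / np.random.chisquare(n - 2)
            ssu = 0.0
            for j in range(m):
                ssu += u[j] * u[j]
            nu = ssu / np.random.chisquare(m - 2)
            if var_upper > 0.0:
                tries = 0
                while nu > var_upper and tries < 1000:
                    nu = ssu / np.random.chisquare(m - 2)
                    tries += 1
                if nu > var_upper:
                    nu = var_upper
            su2 = nu

            # joint scale move on (u, su2): single-site updates mix the
            # SNP-effect variance very slowly (and can trap it near zero),
            # so every few sweeps propose u -> cu, su2 -> c^2 su2 and
            # accept by Metropolis-Hastings; log ratio 2 ln c + dloglik
            if it % 10 == 0:
                g = np.dot(Z, u)
                c = np.exp(0.3 * np.random.normal())
                if var_upper <= 0.0 or c * c * su2 <= var_upper:
                    sse_old = 0.0
                    sse_new = 0.0
                    for i in range(n):
                        sse_old += e[i] * e[i]
                        en = e[i] - (c - 1.0) * g[i]
                        sse_new += en * en
                    logr = 2.0 * np.log(c) - 0.5 * (sse_new - sse_old) / se2
                    if np.log(np.random.random()) < logr:
                        for j in range(m):
                            u[j] *= c
                        su2 *= c * c
                        for i in range(n):
                            e[i] -= (c - 1.0) * g[i]

        if it > burn and (it - burn) % thin == 0:
            g = np.dot(Z, u)
            gm = 0.0
            for i in range(n):
                gm += g[i]
            gm /= n
            ss = 0.0
            for i in range(n):
                ss += (g[i] - gm) ** 2
            varzu = ss / n if pop_var else ss / (n - 1)
            su2_s[isave] = su2
            se2_s[isave] = se2
            varzu_s[isave] = varzu
            for k in range(p):
                beta_s[isave, k] = beta[k]
            for j in range(m):
                u_mean[j] += u[j]
            isave += 1

    if isave > 0:
        for j in range(m):
            u_mean[j] /= isave
    acc_rate = acc_post / prop_post if prop_post > 0 else np.nan
    return su2_s, se2_s, varzu_s, beta_s, u_mean, acc_rate


@njit(cache=True)
def _inv2(a11, a12, a22):
    det = a11 * a22 - a12 * a12
    return a22 / det, -a12 / det, a11 / det


@njit(cache=True)
def _riw2(df, s11, s12, s22):
    """One draw from InvWishart(df, S) for a 2x2 scale matrix S, via the
    Bartlett decomposition of the companion Wishart(df, S^-1)."""
    # jitter guards exact singularity (e.g. duplicated traits)
    eps = 1e-12 * (s11 + s22)
    i11, i12, i22 = _inv2(s11 + eps, s12, s22 + eps)
    l11 = np.sqrt(i11)
    l21 = i12 / l11
    l22 = np.sqrt(max(i22 - l21 * l21, 1e-300))
    a11 = np.sqrt(np.random.chisquare(df))
    a21 = np.random.normal()
    a22 = np.sqrt(np.random.chisquare(df - 1.0))
    # B = L @ A (lower triangular), W = B B'
    b11 = l11 * a11
    b21 = l21 * a11 + l22 * a21
    b22 = l22 * a22
    w11 = b11 * b11
    w12 = b11 * b21
    w22 = b21 * b21 + b22 * b22
    v11, v12, v22 = _inv2(w11, w12, w22)
    return v11, v12, v22


@njit(cache=True)
def _kernel_bivariate(Y, W, Z, n_iter, burn, thin, seed,
                      su11, su12, su22, se11, se12, se22,
                      use_mh):
    np.random.seed(seed)
    n, m = Z.shape
    p = W.shape[1]
    wtw = np.empty(p)
    for k in range(p):
        s = 0.0
        for i in range(n):
            s += W[i, k] * W[i, k]
        wtw[k] = s
    ztz = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Z[i, j] * Z[i, j]
        ztz[j] = s

    beta = np.zeros((p, 2))
    U = np.zeros((m, 2))
    E = Y.copy()

    n_saved = (n_iter - burn) // thin
    su_s = np.empty((n_saved, 3))
    se_s = np.empty((n_saved, 3))
    varzu_s = np.empty((n_saved, 2))
    covzu_s = np.empty(n_saved)
    rg_s = np.empty(n_saved)
    re_s = np.empty(n_saved)
    beta_s = np.empty((n_saved, p, 2))
    u_mean = np.zeros((m, 2))

    step = 0.1 * np.sqrt(0.5 * (su11 + su22))
    acc_win = 0
    prop_win = 0
    acc_post = 0
    prop_post = 0
    isave = 0

    for it in range(1, n_iter + 1):
        si11, si12, si22 = _inv2(se11, se12, se22)
        ui11, ui12, ui22 = _inv2(su11, su12, su22)

        # fixed effects, one coefficient per trait at a time
        for k in range(p):
            for t in range(2):
                bk = beta[k, t]
                stt = si11 if t == 0 else si22
                lin = 0.0
                for i in range(n):
                    if t == 0:
                        lin += W[i, k] * (si11 * E[i, 0] + si12 * E[i, 1])
                    else:
                        lin += W[i, k] * (si12 * E[i, 0] + si22 * E[i, 1])
                lin += stt * wtw[k] * bk
                prec = stt * wtw[k]
                mean = lin / prec
                newb = mean + np.random.normal() / np.sqrt(prec)
                diff = bk - newb
                for i in range(n):
                    E[i, t] += W[i, k] * diff
                beta[k, t] = newb

        # SNP effect 2-vectors from their bivariate normal full conditionals
        for j in range(m):
            u1 = U[j, 0]
            u2 = U[j, 1]
            d1 = 0.0
            d2 = 0.0
            for i in range(n):
                d1 += Z[i, j] * E[i, 0]
                d2 += Z[i, j] * E[i, 1]
            d1 += ztz[j] * u1
            d2 += ztz[j] * u2
            b1 = si11 * d1 + si12 * d2
            b2 = si12 * d1 + si22 * d2
            a11 = ztz[j] * si11 + ui11
            a12 = ztz[j] * si12 + ui12
            a22 = ztz[j] * si22 + ui22
            c11, c12, c22 = _inv2(a11, a12, a22)
            m1 = c11 * b1 + c12 * b2
            m2 = c12 * b1 + c22 * b2
            if use_mh:
                p1 = u1 + step * np.random.normal()
                p2 = u2 + step * np.random.normal()
                q_new = (a11 * (p1 - m1) ** 2 + 2.0 * a12 * (p1 - m1) * (p2 - m2)
                         + a22 * (p2 - m2) ** 2)
                q_old = (a11 * (u1 - m1) ** 2 + 2.0 * a12 * (u1 - m1) * (u2 - m2)
                         + a22 * (u2 - m2) ** 2)
                if it <= burn:
                    prop_win += 1
                else:
                    prop_post += 1
                if np.log(np.random.random()) < -0.5 * (q_new - q_old):
                    if it <= burn:
                        acc_win += 1
                    else:
                        acc_post += 1
                    n1 = p1
                    n2 = p2
                else:
                    n1 = u1
                    n2 = u2
            else:
                l11 = np.sqrt(c11)
                l21 = c12 / l11
                l22 = np.sqrt(max(c22 - l21 * l21, 1e-300))
                z1 = np.random.normal()
                z2 = np.random.normal()
                n1 = m1 + l11 * z1
                n2 = m2 + l21 * z1 + l22 * z2
            df1 = u1 - n1
            df2 = u2 - n2
            for i in range(n):
                E[i, 0] += Z[i, j] * df1
                E[i, 1] += Z[i, j] * df2
            U[j, 0] = n1
            U[j, 1] = n2

        if use_mh and it <= burn and prop_win >= 50 * m:
            rate = acc_win / prop_win
            step *= np.exp(rate - 0.3)
            acc_win = 0
            prop_win = 0

        # residual covariance: inverse-Wishart full conditional, df = n - 3
        s11 = 0.0
        s12 = 0.0
        s22 = 0.0
        for i in range(n):
            s11 += E[i, 0] * E[i, 0]
            s12 += E[i, 0] * E[i, 1]
            s22 += E[i, 1] * E[i, 1]
        se11, se12, se22 = _riw2(n - 3.0, s11, s12, s22)

        # SNP-effect covariance: inverse-Wishart full conditional, df = m - 3
        t11 = 0.0
        t12 = 0.0
        t22 = 0.0
        for j in range(m):
            t11 += U[j, 0] * U[j, 0]
            t12 += U[j, 0] * U[j, 1]
            t22 += U[j, 1] * U[j, 1]
        su11, su12, su22 = _riw2(m - 3.0, t11, t12, t22)

        # per-trait joint scale moves (u_t, Su row/col), as in the
        # univariate sampler; log ratio 3 ln c + dloglik for the 2-trait
        # transform (u_t, su_tt, su_12) -> (c u_t, c^2 su_tt, c su_12)
        if it % 10 == 0:
            si11, si12, si22 = _inv2(se11, se12, se22)
            for tt in range(2):
                g = np.dot(Z, U[:, tt].copy())
                c = np.exp(0.3 * np.random.normal())
                stt = si11 if tt == 0 else si22
                sto = si12
                dq = 0.0
                for i in range(n):
                    a_old = E[i, tt]
                    a_new = a_old - (c - 1.0) * g[i]
                    b = E[i, 1 - tt]
                    dq += stt * (a_new * a_new - a_old * a_old)
                    dq += 2.0 * sto * (a_new - a_old) * b
                logr = 3.0 * np.log(c) - 0.5 * dq
                if np.log(np.random.random()) < logr:
                    for j in range(m):
                        U[j, tt] *= c
                    for i in range(n):
                        E[i, tt] -= (c - 1.0) * g[i]
                    if tt == 0:
                        su11 *= c * c
                    else:
                        su22 *= c * c
                    su12 *= c

        if it > burn and (it - burn) % thin == 0:
            g1 = np.dot(Z, U[:, 0].copy())
            g2 = np.dot(Z, U[:, 1].copy())
            m1g = 0.0
            m2g = 0.0
            for i in range(n):
                m1g += g1[i]
                m2g += g2[i]
            m1g /= n
            m2g /= n
            v1 = 0.0
            v2 = 0.0
            cv = 0.0
            for i in range(n):
                a = g1[i] - m1g
                b = g2[i] - m2g
                v1 += a * a
                v2 += b * b
                cv += a * b
            v1 /= n
            v2 /= n
            cv /= n
            su_s[isave, 0] = su11
            su_s[isave, 1] = su12
            su_s[isave, 2] = su22
            se_s[isave, 0] = se11
            se_s[isave, 1] = se12
            se_s[isave, 2] = se22
            varzu_s[isave, 0] = v1
            varzu_s[isave, 1] = v2
            covzu_s[isave] = cv
            denom = np.sqrt(v1 * v2)
            rg_s[isave] = cv / denom if denom > 0.0 else 0.0
            re_s[isave] = se12 / np.sqrt(se11 * se22)
            for k in range(p):
                beta_s[isave, k, 0] = beta[k, 0]
                beta_s[isave, k, 1] = beta[k, 1]
            for j in range(m):
                u_mean[j, 0] += U[j, 0]
                u_mean[j, 1] += U[j, 1]
            isave += 1

    if isave > 0:
        u_mean /= isave
    acc_rate = acc_post / prop_post if prop_post > 0 else np.nan
    return su_s, se_s, varzu_s, covzu_s, rg_s, re_s, beta_s, u_mean, acc_rate


# ----------------------------------------------------------------------
# public entry points


def run_univariate_chain(
    frame: ModelFrame,
    config: MCMCConfig | None = None,
    fixed_variances: tuple[float, float] | None = None,
) -> tuple[ChainResult, PosteriorSummary]:
    """Sample the univariate SNP-BLUP posterior.

    ``fixed_variances=(su2, se2)`` freezes the variance components (no
    inverse-chi-square updates), which turns the sampler into a draw from
    the known conjugate-normal posterior of the effects - the closed-form
    oracle used in validation.
    """
    if config is None:
        config = MCMCConfig()
    if frame.n_traits != 1:
        raise ValueError("univariate chain needs a single-trait frame")
    if frame.n < 2 or frame.m < 1:
        raise ValueError("need at least two individuals and one SNP")
    vary = float(np.var(frame.y))
    if vary == 0.0:
        raise ValueError("phenotype has zero variance")
    update_vars = fixed_variances is None
    if update_vars and (frame.n < 3 or frame.m < 3):
        raise ValueError("variance updates need n >= 3 and m >= 3")
    if update_vars:
        se2_0 = 0.5 * vary
        # sum_j z_j'z_j / n ~ sum 2p(1-p): the Var(Zu)-to-su2 scale factor
        su2_0 = 0.5 * vary / max(np.sum(frame.Z**2) / frame.n, 1e-12)
    else:
        su2_0, se2_0 = fixed_variances
    var_upper = config.variance_upper_bound if config.variance_upper_bound else -1.0

    t0 = time.time()
    su2_s, se2_s, varzu_s, beta_s, u_mean, acc = _kernel_univariate(
        np.ascontiguousarray(frame.y, dtype=np.float64),
        np.asfortranarray(frame.W, dtype=np.float64),
        np.asfortranarray(frame.Z, dtype=np.float64),
        config.n_iterations, config.burn_in, config.thin,
        config.seed % 2**31, float(su2_0), float(se2_0),
        update_vars, float(var_upper),
        config.sampler == "metropolis_hastings",
        config.var_zu_denominator == "n",
    )
    runtime = time.time() - t0
    h2_s = varzu_s / (varzu_s + se2_s)
    chain = ChainResult(
        trait_names=list(frame.trait_names),
        sigma_u2=su2_s, sigma_e2=se2_s, var_zu=varzu_s, cov_zu=None,
        h2=h2_s, r_genomic=None, r_environmental=None,
        fixed_effects=beta_s, u_posterior_mean=u_mean,
        acceptance_rate=None if np.isnan(acc) else float(acc),
        runtime_seconds=runtime, seed=config.seed,
    )
    logger.info(
        "univariate chain %s: n=%d m=%d iters=%d seed=%d %.1fs acc=%s",
        frame.trait_names[0], frame.n, frame.m, config.n_iterations,
        config.seed, runtime, chain.acceptance_rate,
    )
    return chain, summarize_chain(chain)


def run_bivariate_chain(
    frame: ModelFrame,
    config: MCMCConfig | None = None,
) -> tuple[ChainResult, BivariatePosterior]:
    """Sample the bivariate SNP-BLUP posterior with correlated SNP effects
    and correlated residuals across the two traits."""
    if config is None:
        config = MCMCConfig()
    if frame.n_traits != 2:
        raise ValueError("bivariate chain needs a two-trait frame")
    if frame.n < 4 or frame.m < 4:
        raise ValueError("bivariate sampler needs n >= 4 and m >= 4")
    v1 = float(np.var(frame.y[:, 0]))
    v2 = float(np.var(frame.y[:, 1]))
    if v1 == 0.0 or v2 == 0.0:
        raise ValueError("phenotype has zero variance")
    sz = max(float(np.sum(frame.Z**2) / frame.n), 1e-12)
    su11 = 0.5 * v1 / sz
    su22 = 0.5 * v2 / sz

    t0 = time.time()
    su_s, se_s, varzu_s, covzu_s, rg_s, re_s, beta_s, u_mean, acc = _kernel_bivariate(
        np.ascontiguousarray(frame.y, dtype=np.float64),
        np.asfortranarray(frame.W, dtype=np.float64),
        np.asfortranarray(frame.Z, dtype=np.float64),
        config.n_iterations, config.burn_in, config.thin,
        config.seed % 2**31,
        su11, 0.0, su22, 0.5 * v1, 0.0, 0.5 * v2,
        config.sampler == "metropolis_hastings",
    )
    runtime = time.time() - t0
    h2_s = varzu_s / (varzu_s + se_s[:, [0, 2]])
    chain = ChainResult(
        trait_names=list(frame.trait_names),
        sigma_u2=su_s, sigma_e2=se_s, var_zu=varzu_s, cov_zu=covzu_s,
        h2=h2_s, r_genomic=rg_s, r_environmental=re_s,
        fixed_effects=beta_s, u_posterior_mean=u_mean,
        acceptance_rate=None if np.isnan(acc) else float(acc),
        runtime_seconds=runtime, seed=config.seed,
    )
    logger.info(
        "bivariate chain %s: n=%d m=%d iters=%d seed=%d %.1fs acc=%s",
        "/".join(frame.trait_names), frame.n, frame.m, config.n_iterations,
        config.seed, runtime, chain.acceptance_rate,
    )
    return chain, summarize_chain(chain)


def genomic_variance(Z: np.ndarray, u: np.ndarray, denominator: str = "n") -> np.ndarray | float:
    """Empirical (co)variance over individuals of the genomic values g = Zu.

    For a single effect vector returns a scalar; for a 2-column effect
    matrix returns the 2x2 genomic covariance matrix. The default uses
    the population (n) denominator, matching the per-cycle computation in
    the samplers.
    """
    Z = np.asarray(Z, dtype=float)
    u = np.asarray(u, dtype=float)
    if Z.shape[0] < 2:
        raise ValueError("need at least two individuals")
    g = Z @ u
    ddof = 0 if denominator == "n" else 1
    if g.ndim == 1:
        return float(np.var(g, ddof=ddof))
    gc = g - g.mean(axis=0)
    return (gc.T @ gc) / (g.shape[0] - ddof)


def _geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing the mean of the first and last
    chain segments, with naive (independence) standard errors."""
    n = x.size
    if n < 10:
        return np.nan
    a = x[: max(int(first * n), 2)]
    b = x[-max(int(last * n), 2):]
    denom = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    return float((a.mean() - b.mean()) / denom) if denom > 0 else 0.0


def _ess(x: np.ndarray) -> float:
    import arviz

    with np.errstate(all="ignore"):
        return float(arviz.ess(np.asarray(x)))


def summarize_chain(chain: ChainResult) -> PosteriorSummary | BivariatePosterior:
    """Posterior means and sample (n-1) standard deviations of the derived
    draws, with effective sample size and a Geweke diagnostic attached."""
    if chain.n_saved < 2:
        raise ValueError("need at least two saved draws to summarise")
    if len(chain.trait_names) == 1:
        return PosteriorSummary(
            trait=chain.trait_names[0],
            h2_mean=float(chain.h2.mean()),
            h2_psd=float(chain.h2.std(ddof=1)),
            var_zu_mean=float(chain.var_zu.mean()),
            var_zu_psd=float(chain.var_zu.std(ddof=1)),
            sigma_e2_mean=float(chain.sigma_e2.mean()),
            sigma_e2_psd=float(chain.sigma_e2.std(ddof=1)),
            ess=_ess(chain.h2),
            geweke_z=_geweke_z(chain.h2),
        )
    per_trait = []
    for t in range(2):
        per_trait.append(
            PosteriorSummary(
                trait=chain.trait_names[t],
                h2_mean=float(chain.h2[:, t].mean()),
                h2_psd=float(chain.h2[:, t].std(ddof=1)),
                var_zu_mean=float(chain.var_zu[:, t].mean()),
                var_zu_psd=float(chain.var_zu[:, t].std(ddof=1)),
                sigma_e2_mean=float(chain.sigma_e2[:, 2 * t].mean()),
                sigma_e2_psd=float(chain.sigma_e2[:, 2 * t].std(ddof=1)),
                ess=_ess(chain.h2[:, t]),
                geweke_z=_geweke_z(chain.h2[:, t]),
            )
        )
    return BivariatePosterior(
        genomic_correlation_mean=float(chain.r_genomic.mean()),
        genomic_correlation_psd=float(chain.r_genomic.std(ddof=1)),
        environmental_correlation_mean=float(chain.r_environmental.mean()),
        environmental_correlation_psd=float(chain.r_environmental.std(ddof=1)),
        traits=per_trait,
    )
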