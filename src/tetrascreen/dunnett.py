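"""Dunnett many-to-one comparison for the confirmatory screen.

Each rescreened gene's replicate scores are compared against the shared
R-LUC negative controls with the classical (pooled-variance) Dunnett test:

    T_i = (mean_i - mean_ctrl) / (s_pooled * sqrt(1/n_i + 1/n_ctrl))

Under the complete null the T_i follow an equicorrelated multivariate t
with correlation lambda_i * lambda_j, lambda_i = sqrt(n_i / (n_i + n_ctrl)),
and the adjusted p-value of contrast i is P(max_j T_j >= T_i) (one-sided)
or P(max_j |T_j| >= |T_i|) (two-sided).  The probability is evaluated either
by deterministic two-level Gauss-Legendre quadrature over the pooled-SD and
control-mean nuisance variables, or by seeded Monte-Carlo simulation of the
max-T null with a reported standard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import stats


@dataclass
class DunnettResult:
    """One gene's many-to-one comparison against the shared controls."""

    gene: str
    diff: float  # mean difference vs control, in score units
    t_stat: float
    p_adj: float
    k: int  # number of simultaneous comparisons in the family
    sided: str
    mc_se: float | None = None  # Monte-Carlo SE of p_adj, when applicable


def _quad_nodes(n: int, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights mapped to [lo, hi]."""
    x, w = leggauss(n)
    return 0.5 * (hi - lo) * (x + 1.0) + lo, 0.5 * (hi - lo) * w


def _chi_weights(n_nodes: int, df: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and density-weighted quadrature weights for U = s/sigma.

    U^2 ~ chi2_df / df; the density is evaluated in log space and the range
    truncated at the 1e-12 tail quantiles (negligible mass, smooth
    integrand, so Gauss-Legendre converges spectrally).
    """
    from scipy.special import gammaln

    lo, hi = np.sqrt(stats.chi2.ppf([1e-12, 1 - 1e-12], df) / df)
    u, w = _quad_nodes(n_nodes, lo, hi)
    log_f = (
        np.log(2.0)
        + 0.5 * df * np.log(df / 2.0)
        - gammaln(df / 2.0)
        + (df - 1) * np.log(u)
        - df * u * u / 2.0
    )
    return u, w * np.exp(log_f)


def _p_max_t(
    t: np.ndarray,
    ns: np.ndarray,
    n0: int,
    df: int,
    sided: str = "greater",
    n_nodes: int = 160,
) -> np.ndarray:
    """P(max_j T_j >= t) (or max |T_j| >= |t|) under the Dunnett null.

    Integrates over the probability transforms of the pooled-scale variable
    U = s/sigma (U^2 ~ chi2_df / df) and the control-mean standard normal Z:

        P(all T_j < t) = E_{U,Z}[ prod_j Phi(sqrt(n_j) (t U c_j + Z/sqrt(n0))) ]

    with c_j = sqrt(1/n_j + 1/n0).
    """
    if sided not in ("greater", "two-sided"):
        raise ValueError(f"unknown sidedness: {sided!r}")
    t = np.atleast_1d(np.asarray(t, dtype=float))
    u, wu = _chi_weights(n_nodes, df)  # pooled-SD nodes, density-weighted
    z, wz = _quad_nodes(n_nodes, -8.5, 8.5)  # control-mean nodes
    wz = wz * stats.norm.pdf(z)
    c = np.sqrt(1.0 / ns + 1.0 / n0)
    sqn = np.sqrt(ns)
    zz = z[None, :] / np.sqrt(n0)  # (1, z)
    equal_n = bool(np.all(ns == ns[0]))
    k = len(ns)

    out = np.empty(len(t))
    for i, ti in enumerate(t):
        tu = ti * u[:, None]  # (u, z) after broadcast with zz
        if equal_n:
            if sided == "greater":
                prod = stats.norm.cdf(sqn[0] * (tu * c[0] + zz)) ** k
            else:
                ta = np.abs(tu)
                prod = (
                    stats.norm.cdf(sqn[0] * (ta * c[0] + zz))
                    - stats.norm.cdf(sqn[0] * (-ta * c[0] + zz))
                ) ** k
        else:
            # axes (u, z, group)
            tug = tu[:, :, None] * c
            zg = zz[:, :, None]
            if sided == "greater":
                inner = stats.norm.cdf(sqn * (tug + zg))
            else:
                ta = np.abs(tug)
                inner = stats.norm.cdf(sqn * (ta + zg)) - stats.norm.cdf(sqn * (-ta + zg))
            prod = np.prod(inner, axis=-1)
        out[i] = np.einsum("uz,u,z->", prod, wu, wz)
    return np.clip(1.0 - out, 0.0, 1.0)


def _mc_max_t(
    ns: np.ndarray, n0: int, df: int, reps: int, rng: np.random.Generator, sided: str
) -> np.ndarray:
    """Seeded Monte-Carlo sample of the null max-T distribution."""
    k = len(ns)
    z0 = rng.standard_normal(reps)
    zg = rng.standard_normal((reps, k))
    u = np.sqrt(rng.chisquare(df, size=reps) / df)
    c = np.sqrt(1.0 / ns + 1.0 / n0)
    t = (zg / np.sqrt(ns) - z0[:, None] / np.sqrt(n0)) / (u[:, None] * c)
    return np.max(np.abs(t), axis=1) if sided == "two-sided" else np.max(t, axis=1)


def dunnett_adjusted_p(
    group_scores: dict[str, np.ndarray],
    control_scores: np.ndarray,
    sided: str = "greater",
    method: str = "auto",
    mc_reps: int = 200_000,
    seed: int | None = None,
    n_nodes: int = 160,
) -> list[DunnettResult]:
    """Dunnett-adjusted p-values for every gene against the shared control.

    ``method``: "integration" (deterministic quadrature), "montecarlo"
    (seeded, with reported SE), or "auto" (integration for k <= 50).
    Requires >= 2 observations per gene and control, and positive pooled
    variance.
    """
    genes = list(group_scores)
    k = len(genes)
    if k == 0:
        return []
    ctrl = np.asarray(control_scores, dtype=float)
    groups = [np.asarray(group_scores[g], dtype=float) for g in genes]
    if len(ctrl) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 observations per gene and >= 2 controls")
    ns = np.array([len(g) for g in groups])
    n0 = len(ctrl)
    df = int(ns.sum() - k + n0 - 1)
    if df < 1:
        raise ValueError("not enough observations for df >= 1")
    ss = sum(((g - g.mean()) ** 2).sum() for g in groups) + ((ctrl - ctrl.mean()) ** 2).sum()
    s2 = ss / df
    if s2 <= 0:
        raise ValueError("zero pooled variance; Dunnett statistics undefined")
    sp = np.sqrt(s2)
    diffs = np.array([g.mean() - ctrl.mean() for g in groups])
    tstats = diffs / (sp * np.sqrt(1.0 / ns + 1.0 / n0))

    if method == "auto":
        method = "integration" if k <= 50 else "montecarlo"
    if method == "integration":
        ts = tstats if sided == "greater" else np.abs(tstats)
        p = _p_max_t(ts, ns, n0, df, sided=sided, n_nodes=n_nodes)
        se = [None] * k
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        max_t = _mc_max_t(ns, n0, df, mc_reps, rng, sided)
        ts = tstats if sided == "greater" else np.abs(tstats)
        p = np.array([(max_t >= t).mean() for t in ts])
        se = [float(np.sqrt(pi * (1 - pi) / mc_reps)) for pi in p]
    else:
        raise ValueError(f"unknown method: {method!r}")

    return [
        DunnettResult(
            gene=g, diff=float(d), t_stat=float(t), p_adj=float(pi), k=k, sided=sided, mc_se=s
        )
        for g, d, t, pi, s in zip(genes, diffs, tstats, p, se)
    ]


def dunnett_critical_value(
    k: int,
    ns: int | np.ndarray,
    n0: int,
    df: int,
    alpha: float = 0.1,
    sided: str = "greater",
    n_nodes: int = 160,
) -> float:
    """Critical max-T value t* with P(max_j T_j >= t*) = alpha under the null."""
    from scipy.optimize import brentq

    ns_arr = np.full(k, ns) if np.isscalar(ns) else np.asarray(ns)

    def f(t: float) -> float:
        return float(_p_max_t(np.array([t]), ns_arr, n0, df, sided=sided, n_nodes=n_nodes)[0]) - alpha

    return float(brentq(f, -10.0, 40.0, xtol=1e-10))


def confirm_hits(results: list[DunnettResult], alpha: float = 0.1) -> list[str]:
    """Genes confirmed at adjusted p strictly below ``alpha``.

    Confirmation additionally requires the difference to point in the
    improving direction (positive mean difference vs control).
    """
    return [r.gene for r in results if r.p_adj < alpha and r.diff > 0]


def confirmation_rate(n_confirmed: int, n_tested: int) -> tuple[int, Fraction]:
    """Confirmation rate as (nearest-integer percent, exact ratio).

    E.g. 157 confirmed of 374 tested gives (42, Fraction(157, 374)).
    """
    if n_tested <= 0:
        raise ValueError("n_tested must be > 0")
    if not 0 <= n_confirmed <= n_tested:
        raise ValueError("need 0 <= n_confirmed <= n_tested")
    frac = Fraction(n_confirmed, n_tested)
    return int(round(100 * n_confirmed / n_tested)), frac
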