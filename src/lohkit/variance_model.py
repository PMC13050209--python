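"""Nested GLMMs for per-arm event counts and cis/trans variance partitioning.

The per-generation event rate on arm ``a`` of hybrid ``h`` is modelled as

    lambda_hca = mu + alpha_h * L_a + beta_a + gamma_ha

with fixed effects ``mu`` (baseline) and ``alpha_h`` (per-hybrid slope on
arm length: segregating trans factors), and zero-mean normal random effects
``beta_a`` (arm effects shared across hybrids: fixed cis factors, SD
``sigma_fc``) and ``gamma_ha`` (hybrid-by-arm effects: segregating cis
factors, SD ``sigma_sc``).  The expected count over ``T_h`` generations is
``f(lambda * T_h)`` where ``f`` inverts a stitched link that keeps the
Poisson mean (or Bernoulli probability) positive for any predictor value.

Fitting maximizes the Laplace-approximate marginal likelihood: fixed
effects and the conditional modes of the random effects are optimized
jointly in an inner problem; the two variance parameters in an outer
Nelder-Mead.  The log-determinant of the random-effects Hessian exploits
the arrow structure (``gamma`` is per-cell, so its block is diagonal and
``beta`` couples only to its own arm's cells), making each outer
evaluation O(cells).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

logger = logging.getLogger(__name__)

__all__ = [
    "CountTable",
    "IdentityLogLink",
    "BernoulliStitchLink",
    "link_iloh",
    "link_tloh",
    "GlmmFit",
    "fit_glmm",
    "fixed_effect_se",
    "lrt",
    "partition_variance",
    "VariancePartition",
    "gtest_long_arms",
]

Family = Literal["poisson_iloh", "bernoulli_tloh"]
Model = Literal["full", "arm", "hybrid_slopes", "hybrid_arm", "one_slope"]

_LENGTH_SCALE = 1e6  # arm lengths enter the linear predictor in Mb


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Event counts per (hybrid, clone, arm).

    Built from a long table with one row per clone x arm.  Arms and hybrids
    are coded densely; ``arm_bp`` is indexed by arm code and ``generations``
    by hybrid code.
    """

    hybrid: np.ndarray  # int codes per observation
    clone: np.ndarray  # int codes per observation (within hybrid)
    arm: np.ndarray  # int codes per observation
    count: np.ndarray
    arm_bp: np.ndarray  # length A
    generations: np.ndarray  # length H
    hybrid_names: list[str] = field(default_factory=list)
    arm_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hybrid = np.asarray(self.hybrid, dtype=np.int64)
        self.clone = np.asarray(self.clone, dtype=np.int64)
        self.arm = np.asarray(self.arm, dtype=np.int64)
        self.count = np.asarray(self.count, dtype=np.int64)
        self.arm_bp = np.asarray(self.arm_bp, dtype=float)
        self.generations = np.asarray(self.generations, dtype=float)
        if np.any(self.count < 0):
            raise ValueError("counts must be non-negative")
        if not self.hybrid_names:
            self.hybrid_names = [f"h{i}" for i in range(self.n_hybrids)]
        if not self.arm_names:
            self.arm_names = [f"arm{i}" for i in range(self.n_arms)]

    @property
    def n_hybrids(self) -> int:
        return int(self.hybrid.max()) + 1 if len(self.hybrid) else 0

    @property
    def n_arms(self) -> int:
        return int(self.arm.max()) + 1 if len(self.arm) else 0

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountTable":
        """Build from columns hybrid, clone, arm, count, arm_bp, generations."""
        need = {"hybrid", "clone", "arm", "count", "arm_bp", "generations"}
        if not need.issubset(df.columns):
            raise ValueError(f"count table needs columns {sorted(need)}")
        hcodes, hnames = pd.factorize(df["hybrid"], sort=True)
        acodes, anames = pd.factorize(df["arm"], sort=True)
        arm_bp = np.zeros(len(anames))
        arm_bp[acodes] = df["arm_bp"].to_numpy(float)
        gens = np.zeros(len(hnames))
        gens[hcodes] = df["generations"].to_numpy(float)
        clone_codes = (
            df.groupby("hybrid", sort=False)["clone"]
            .transform(lambda s: pd.factorize(s)[0])
            .to_numpy()
        )
        return cls(
            hybrid=hcodes,
            clone=clone_codes,
            arm=acodes,
            count=df["count"].to_numpy(),
            arm_bp=arm_bp,
            generations=gens,
            hybrid_names=[str(x) for x in hnames],
            arm_names=[str(x) for x in anames],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hybrid": [self.hybrid_names[h] for h in self.hybrid],
                "clone": self.clone,
                "arm": [self.arm_names[a] for a in self.arm],
                "count": self.count,
                "arm_bp": self.arm_bp[self.arm],
                "generations": self.generations[self.hybrid],
            }
        )

    def cells(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Sufficient statistics per (hybrid, arm) cell.

        Returns ``(h_idx, a_idx, S, n)`` where ``S`` sums counts over the
        clones of the cell and ``n`` counts the clones.
        """
        key = self.hybrid * self.n_arms + self.arm
        uniq, inv = np.unique(key, return_inverse=True)
        S = np.bincount(inv, weights=self.count.astype(float))
        n = np.bincount(inv).astype(float)
        return uniq // self.n_arms, uniq % self.n_arms, S, n


# ---------------------------------------------------------------------------
# Stitched link functions
# ---------------------------------------------------------------------------


class IdentityLogLink:
    """Identity link stitched to a logarithm below ``delta`` (Poisson case).

    ``g(y) = y`` for ``y >= delta`` and ``g(y) = delta + delta*ln(y/delta)``
    for ``0 < y < delta``; continuously differentiable at the stitch.  The
    inverse ``f = g^-1`` is positive everywhere.
    """

    def __init__(self, delta: float = 0.01):
        if delta <= 0:
            raise ValueError("delta must be positive")
        self.delta = delta

    def g(self, y):
        y = np.asarray(y, dtype=float)
        if np.any(y <= 0):
            raise ValueError("g is defined for y > 0")
        d = self.delta
        out = y.astype(float).copy()
        lo = y < d
        out[lo] = d + d * np.log(y[lo] / d)
        return out

    def f(self, x):
        x = np.asarray(x, dtype=float)
        d = self.delta
        out = x.astype(float).copy()
        lo = x < d
        out[lo] = d * np.exp((x[lo] - d) / d)
        return out

    def fp(self, x):
        x = np.asarray(x, dtype=float)
        d = self.delta
        out = np.ones_like(x, dtype=float)
        lo = x < d
        out[lo] = np.exp((x[lo] - d) / d)
        return out

    def fpp(self, x):
        x = np.asarray(x, dtype=float)
        d = self.delta
        out = np.zeros_like(x, dtype=float)
        lo = x < d
        out[lo] = np.exp((x[lo] - d) / d) / d
        return out

    # log f and its derivatives, stable for arbitrarily negative predictors
    def logf(self, x):
        x = np.asarray(x, dtype=float)
        d = self.delta
        out = np.empty_like(x, dtype=float)
        hi = x >= d
        out[hi] = np.log(x[hi])
        out[~hi] = np.log(d) + (x[~hi] - d) / d
        return out

    def dlogf(self, x):
        x = np.asarray(x, dtype=float)
        d = self.delta
        return np.where(x >= d, 1.0 / np.maximum(x, d), 1.0 / d)

    def d2logf(self, x):
        x = np.asarray(x, dtype=float)
        d = self.delta
        return np.where(x >= d, -1.0 / np.maximum(x, d) ** 2, 0.0)


class BernoulliStitchLink:
    """Complementary-log link stitched to an exponential lower branch.

    ``g(y) = -ln(1 - y)`` for ``eps <= y < 1`` with ``eps = 1 - exp(-delta)``
    and ``g(y) = delta + eps*e^delta * ln(y/eps)`` below; the inverse gives
    ``p = 1 - exp(-x)`` for ``x >= delta`` and
    ``p = eps * exp((x - delta)/(eps*e^delta))`` otherwise, positive for
    any predictor and continuously differentiable at the stitch (both
    branches have slope ``e^-delta`` at ``x = delta``).
    """

    def __init__(self, delta: float = 0.03):
        if delta <= 0:
            raise ValueError("delta must be positive")
        self.delta = delta
        self.eps = -np.expm1(-delta)  # 1 - e^-delta
        self._c = self.eps * np.exp(delta)

    def g(self, y):
        y = np.asarray(y, dtype=float)
        if np.any((y <= 0) | (y >= 1)):
            raise ValueError("g is defined for 0 < y < 1")
        d, e = self.delta, self.eps
        out = np.empty_like(y, dtype=float)
        hi = y >= e
        out[hi] = -np.log1p(-y[hi])
        out[~hi] = d + self._c * np.log(y[~hi] / e)
        return out

    def f(self, x):
        x = np.asarray(x, dtype=float)
        d, e = self.delta, self.eps
        out = np.empty_like(x, dtype=float)
        hi = x >= d
        out[hi] = -np.expm1(-x[hi])
        out[~hi] = e * np.exp((x[~hi] - d) / self._c)
        return out

    def fp(self, x):
        x = np.asarray(x, dtype=float)
        d, e = self.delta, self.eps
        out = np.empty_like(x, dtype=float)
        hi = x >= d
        out[hi] = np.exp(-x[hi])
        out[~hi] = (e / self._c) * np.exp((x[~hi] - d) / self._c)
        return out

    def fpp(self, x):
        x = np.asarray(x, dtype=float)
        d, e = self.delta, self.eps
        out = np.empty_like(x, dtype=float)
        hi = x >= d
        out[hi] = -np.exp(-x[hi])
        out[~hi] = (e / self._c**2) * np.exp((x[~hi] - d) / self._c)
        return out

    def logf(self, x):
        x = np.asarray(x, dtype=float)
        d, e = self.delta, self.eps
        out = np.empty_like(x)
        hi = x >= d
        out[hi] = np.log(-np.expm1(-x[hi]))
        out[~hi] = np.log(e) + (x[~hi] - d) / self._c
        return out

    def dlogf(self, x):
        x = np.asarray(x, dtype=float)
        d = self.delta
        out = np.empty_like(x)
        hi = x >= d
        out[hi] = 1.0 / np.expm1(x[hi])
        out[~hi] = 1.0 / self._c
        return out

    def d2logf(self, x):
        x = np.asarray(x, dtype=float)
        d = self.delta
        out = np.zeros_like(x)
        hi = x >= d
        ex = np.expm1(x[hi])
        out[hi] = -(ex + 1.0) / ex**2
        return out


def link_iloh(delta: float = 0.01) -> IdentityLogLink:
    return IdentityLogLink(delta)


def link_tloh(delta: float = 0.03) -> BernoulliStitchLink:
    return BernoulliStitchLink(delta)


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------


def _cell_terms(family: Family, S, n, link, xi):
    """Per-cell log-likelihood and its first two derivatives w.r.t. xi.

    Works in log space through the link so that arbitrarily negative
    predictors (mean underflowing to zero) stay finite.
    """
    if family == "poisson_iloh":
        m = link.f(xi)
        ll = S * link.logf(xi) - n * m
        d1 = S * link.dlogf(xi) - n * link.fp(xi)
        d2 = S * link.d2logf(xi) - n * link.fpp(xi)
        return ll, d1, d2
    p = link.f(xi)
    one_minus = np.maximum(1.0 - p, 1e-300)
    fp = link.fp(xi)
    fpp = link.fpp(xi)
    nf = n - S
    ll = S * link.logf(xi) + nf * np.log(one_minus)
    d1 = S * link.dlogf(xi) - nf * fp / one_minus
    d2 = S * link.d2logf(xi) - nf * (fpp * one_minus + fp**2) / one_minus**2
    return ll, d1, d2


class _Design:
    """Per-cell design bookkeeping for one model variant."""

    def __init__(self, table: CountTable, model: Model):
        self.model = model
        h, a, S, n = table.cells()
        self.h, self.a, self.S, self.n = h, a, S, n
        self.T = table.generations[h]
        # internal parameters are expressed per Tbar generations so that the
        # optimizer works on O(0.1) quantities; ``Trel`` rescales per cell
        self.Tbar = float(np.mean(table.generations))
        self.Trel = self.T / self.Tbar
        self.L = table.arm_bp[a] / _LENGTH_SCALE
        self.H = table.n_hybrids
        self.A = table.n_arms
        self.n_cells = len(S)

        if model in ("full", "arm", "hybrid_slopes"):
            self.n_fixed = 1 + self.H
        elif model == "one_slope":
            self.n_fixed = 2
        elif model == "hybrid_arm":
            self.n_fixed = 1
        else:
            raise ValueError(f"unknown model {model!r}")
        self.has_beta = model in ("full", "arm")
        self.has_gamma = model in ("full", "hybrid_arm")
        self.n_beta = self.A if self.has_beta else 0
        self.n_gamma = self.n_cells if self.has_gamma else 0
        self.n_params = self.n_fixed + self.n_beta + self.n_gamma

    def linpred(self, z: np.ndarray) -> np.ndarray:
        phi = z[: self.n_fixed]
        eta = np.full(self.n_cells, phi[0])
        if self.model in ("full", "arm", "hybrid_slopes"):
            eta = eta + phi[1 + self.h] * self.L
        elif self.model == "one_slope":
            eta = eta + phi[1] * self.L
        if self.has_beta:
            eta = eta + z[self.n_fixed : self.n_fixed + self.n_beta][self.a]
        if self.has_gamma:
            eta = eta + z[self.n_fixed + self.n_beta :]
        return eta

    def fixed_only(self, z: np.ndarray) -> np.ndarray:
        phi = z[: self.n_fixed]
        eta = np.full(self.n_cells, phi[0])
        if self.model in ("full", "arm", "hybrid_slopes"):
            eta = eta + phi[1 + self.h] * self.L
        elif self.model == "one_slope":
            eta = eta + phi[1] * self.L
        return eta

    def accumulate_grad(self, u: np.ndarray, z: np.ndarray, s_fc, s_sc) -> np.ndarray:
        """Gradient of the penalized loglik; ``u = dll/deta`` per cell."""
        grad = np.zeros(self.n_params)
        grad[0] = u.sum()
        if self.model in ("full", "arm", "hybrid_slopes"):
            np.add.at(grad, 1 + self.h, u * self.L)
        elif self.model == "one_slope":
            grad[1] = np.sum(u * self.L)
        off = self.n_fixed
        if self.has_beta:
            np.add.at(grad, off + self.a, u)
            grad[off : off + self.n_beta] -= z[off : off + self.n_beta] / s_fc**2
            off += self.n_beta
        if self.has_gamma:
            grad[off:] = u - z[off:] / s_sc**2
        return grad


def _penalized_negloglik(
    z, design: _Design, family: Family, link, s_fc, s_sc
) -> tuple[float, np.ndarray]:
    eta = design.linpred(z)
    xi = eta * design.Trel
    ll_cells, d1, _ = _cell_terms(family, design.S, design.n, link, xi)
    ll = float(np.sum(ll_cells))
    off = design.n_fixed
    if design.has_beta:
        b = z[off : off + design.n_beta]
        ll -= 0.5 * float(np.sum(b**2)) / s_fc**2 + design.n_beta * np.log(s_fc)
        off += design.n_beta
    if design.has_gamma:
        g = z[off:]
        ll -= 0.5 * float(np.sum(g**2)) / s_sc**2 + design.n_gamma * np.log(s_sc)
    u = d1 * design.Trel
    grad = design.accumulate_grad(u, z, s_fc, s_sc)
    return -ll, -grad


def _cell_curvatures(z, design: _Design, family: Family, link) -> np.ndarray:
    """``w = -d^2 ll / deta^2`` per cell at z."""
    eta = design.linpred(z)
    xi = eta * design.Trel
    _, _, d2 = _cell_terms(family, design.S, design.n, link, xi)
    return -d2 * design.Trel**2


def _laplace_logdet(w, design: _Design, s_fc, s_sc) -> float:
    """log det of the random-effects Hessian via the arrow structure."""
    logdet = 0.0
    if design.has_gamma:
        hg = w + 1.0 / s_sc**2
        if np.any(hg <= 0):
            return np.inf
        logdet += float(np.sum(np.log(hg)))
    if design.has_beta:
        if design.has_gamma:
            hg = w + 1.0 / s_sc**2
            corr = w - w**2 / hg  # Schur complement contribution per cell
        else:
            corr = w
        diag = np.bincount(design.a, weights=corr, minlength=design.A) + 1.0 / s_fc**2
        if np.any(diag <= 0):
            return np.inf
        logdet += float(np.sum(np.log(diag)))
    return logdet


@dataclass
class GlmmFit:
    """Fitted GLMM with Laplace-approximate log marginal likelihood."""

    model: Model
    family: Family
    delta: float
    mu: float
    alpha: np.ndarray  # per-hybrid slope (per Mb of arm length); len 1 for one_slope
    sigma_fc: float
    sigma_sc: float
    beta: np.ndarray  # conditional modes per arm
    gamma: np.ndarray  # conditional modes per cell
    loglik: float
    converged: bool
    n_obs: int
    frac_predictor_below_delta: float
    _design: _Design | None = None
    _z: np.ndarray | None = None

    @property
    def alpha_per_bp(self) -> np.ndarray:
        return self.alpha / _LENGTH_SCALE

    def cell_means(self, level: str = "full") -> np.ndarray:
        """Per-cell expected counts at a given prediction level.

        ``level`` is one of ``fixed`` (fixed effects only), ``arm`` (fixed
        plus arm effects) or ``full`` (all effects).
        """
        d = self._design
        if d is None:
            raise ValueError("fit was not built with a retained design")
        link = _make_link(self.family, self.delta)
        eta = d.fixed_only(self._z)
        if level in ("arm", "full") and d.has_beta:
            eta = eta + self._z[d.n_fixed : d.n_fixed + d.n_beta][d.a]
        if level == "full" and d.has_gamma:
            eta = eta + self._z[d.n_fixed + d.n_beta :]
        return link.f(eta * d.Trel)


def _make_link(family: Family, delta: float):
    return IdentityLogLink(delta) if family == "poisson_iloh" else BernoulliStitchLink(delta)


def _default_delta(family: Family) -> float:
    return 0.01 if family == "poisson_iloh" else 0.03


def _loglik_constant(table: CountTable, family: Family) -> float:
    if family == "poisson_iloh":
        return -float(np.sum(special.gammaln(table.count + 1.0)))
    return 0.0


def fit_glmm(
    table: CountTable,
    family: Family,
    model: Model = "full",
    delta: float | None = None,
    seed: int = 0,
    max_outer: int = 200,
    tol: float = 1e-8,
) -> GlmmFit:
    """Fit one of the nested models by Laplace-approximate ML.

    The inner problem (fixed effects plus conditional modes of the random
    effects) is solved with L-BFGS with analytic gradients; the outer
    problem over ``(log sigma_fc, log sigma_sc)`` with Nelder-Mead, started
    from moderate values and warm-starting the inner solution.  ``seed``
    fixes the (deterministic) jitter of the starting point and is recorded
    for reproducibility.
    """
    if delta is None:
        delta = _default_delta(family)
    if family == "bernoulli_tloh" and np.any(table.count > 1):
        raise ValueError("tLOH counts must be 0/1")
    link = _make_link(family, delta)
    design = _Design(table, model)
    const = _loglik_constant(table, family)
    rng = np.random.default_rng(seed)

    # starting fixed effects: method-of-moments on per-hybrid mean counts,
    # expressed in the internal per-Tbar-generation units
    h_all, a_all, S, n = design.h, design.a, design.S, design.n
    z = np.zeros(design.n_fixed + design.n_beta + design.n_gamma)
    per_h = np.zeros(design.H)
    for h in range(design.H):
        sel = h_all == h
        mean_count = np.sum(S[sel]) / np.sum(n[sel])
        if family == "bernoulli_tloh":
            mean_count = min(mean_count, 0.95)
            mean_count = -np.log1p(-mean_count)
        per_h[h] = max(mean_count, 1e-3) / design.Trel[sel][0]
    mean_L = float(design.L.mean())
    mu0 = 0.5 * float(per_h.mean())
    z[0] = mu0
    if model in ("full", "arm", "hybrid_slopes"):
        z[1 : 1 + design.H] = np.maximum((per_h - mu0) / mean_L, 1e-6)
    elif model == "one_slope":
        z[1] = max((float(per_h.mean()) - mu0) / mean_L, 1e-6)
    z[: design.n_fixed] *= 1.0 + 0.01 * rng.standard_normal(design.n_fixed)

    def inner(log_s: np.ndarray, z0: np.ndarray) -> tuple[float, np.ndarray]:
        s_fc = float(np.exp(log_s[0])) if design.has_beta else 1.0
        s_sc = float(np.exp(log_s[-1])) if design.has_gamma else 1.0
        res = optimize.minimize(
            _penalized_negloglik,
            z0,
            args=(design, family, link, s_fc, s_sc),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": tol, "gtol": 1e-7},
        )
        zhat = res.x
        ll_pen = -res.fun
        q = design.n_beta + design.n_gamma
        if q == 0:
            return ll_pen, zhat
        w = _cell_curvatures(zhat, design, family, link)
        logdet = _laplace_logdet(w, design, s_fc, s_sc)
        if not np.isfinite(logdet):
            return -np.inf, zhat
        # ll_pen carries the normal densities without their (2 pi) constants,
        # which cancel exactly against the Laplace volume factor, leaving
        # log ML ~= ll_pen - log det(H) / 2
        return ll_pen - 0.5 * logdet, zhat

    n_var = int(design.has_beta) + int(design.has_gamma)
    if n_var == 0:
        ll, z = inner(np.zeros(0), z)
        res = optimize.minimize(
            _penalized_negloglik,
            z,
            args=(design, family, link, 1.0, 1.0),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 5000, "ftol": tol},
        )
        z = res.x
        ll = -res.fun
        s_fc = s_sc = 0.0
        converged = bool(res.success)
    else:
        state = {"z": z.copy()}

        def outer_obj(log_s):
            log_s = np.clip(log_s, -12.0, 4.0)
            ll, zhat = inner(log_s, state["z"])
            if np.isfinite(ll):
                state["z"] = zhat
            return -ll if np.isfinite(ll) else 1e12

        x0 = np.full(n_var, np.log(0.3 * max(mu0, 1e-2)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = optimize.minimize(
                outer_obj,
                x0,
                method="Nelder-Mead",
                options={"maxiter": max_outer, "xatol": 1e-4, "fatol": 1e-7},
            )
        # guard against outer local optima: also evaluate the boundary
        # (each variance component switched off), which recovers the nested
        # model's likelihood, and keep the best candidate
        candidates = [np.clip(out.x, -12.0, 4.0)]
        for i in range(n_var):
            c = np.clip(out.x.copy(), -12.0, 4.0)
            c[i] = -12.0
            candidates.append(c)
        if n_var == 2:
            candidates.append(np.full(2, -12.0))
        ll, log_s, z = -np.inf, candidates[0], state["z"]
        for cand in candidates:
            ll_c, z_c = inner(cand, state["z"])
            if np.isfinite(ll_c) and ll_c > ll:
                ll, log_s, z = ll_c, cand, z_c
        s_fc = float(np.exp(log_s[0])) if design.has_beta else 0.0
        s_sc = float(np.exp(log_s[-1])) if design.has_gamma else 0.0
        # report variance components at the lower boundary as exact zeros
        if design.has_beta and log_s[0] <= -11.0:
            s_fc = 0.0
        if design.has_gamma and log_s[-1] <= -11.0:
            s_sc = 0.0
        converged = bool(np.isfinite(ll))
    if not converged:
        raise RuntimeError(f"GLMM fit did not converge for model {model!r}")

    # convert internal (per-Tbar-generation) parameters back to per-generation
    Tbar = design.Tbar
    phi = z[: design.n_fixed]
    beta = (
        z[design.n_fixed : design.n_fixed + design.n_beta] / Tbar
        if design.has_beta
        else np.zeros(design.A)
    )
    gamma = (
        z[design.n_fixed + design.n_beta :] / Tbar
        if design.has_gamma
        else np.zeros(design.n_cells)
    )
    xi_fixed = design.fixed_only(z) * design.Trel
    frac_below = float(np.mean(xi_fixed < delta))

    if model == "one_slope":
        alpha = np.array([phi[1]]) / Tbar
    elif model == "hybrid_arm":
        alpha = np.zeros(1)
    else:
        alpha = phi[1:] / Tbar

    return GlmmFit(
        model=model,
        family=family,
        delta=delta,
        mu=float(phi[0]) / Tbar,
        alpha=alpha,
        sigma_fc=s_fc / Tbar,
        sigma_sc=s_sc / Tbar,
        beta=beta,
        gamma=gamma,
        loglik=float(ll + const),
        converged=converged,
        n_obs=len(table.count),
        frac_predictor_below_delta=frac_below,
        _design=design,
        _z=z,
    )


def fixed_effect_se(fit: GlmmFit) -> dict[str, np.ndarray]:
    """Standard errors of the fixed effects from the observed information.

    Exact for the models without random effects; for mixed models this is
    the profile (conditional-mode) information and slightly optimistic.
    Returned on the per-generation scale, ``alpha`` per Mb of arm length.
    """
    d = fit._design
    if d is None:
        raise ValueError("fit lacks its design; refit with fit_glmm")
    link = _make_link(fit.family, fit.delta)
    w = _cell_curvatures(fit._z, d, fit.family, link)
    X = np.zeros((d.n_cells, d.n_fixed))
    X[:, 0] = 1.0
    if d.model in ("full", "arm", "hybrid_slopes"):
        for h in range(d.H):
            X[d.h == h, 1 + h] = d.L[d.h == h]
    elif d.model == "one_slope":
        X[:, 1] = d.L
    info = X.T @ (w[:, None] * X)
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0)) / d.Tbar
    return {"mu": se[0], "alpha": se[1:]}


def lrt(
    model_small: GlmmFit,
    model_big: GlmmFit,
    df: int,
    boundary: bool = False,
    tol: float = 1e-3,
) -> float:
    """Likelihood-ratio test p-value for nested fits.

    With ``boundary=True`` the null distribution is the 50:50 mixture of
    chi-squared with ``df`` and ``df - 1`` degrees of freedom (variance
    parameter tested on its boundary); off by default.
    """
    stat = 2.0 * (model_big.loglik - model_small.loglik)
    # Laplace + numerical optimization introduce O(1)-nat noise; a mildly
    # negative statistic is clipped to zero (conservative, p = 1), while a
    # clearly negative one signals a failed fit
    if stat < -max(2.0, tol * abs(model_big.loglik)):
        raise ValueError(
            f"larger model has lower log-likelihood (stat = {stat:.4g}); fit failure"
        )
    stat = max(stat, 0.0)
    if not boundary:
        return float(stats.chi2.sf(stat, df))
    lower = stats.chi2.sf(stat, df - 1) if df > 1 else float(stat <= 0)
    return float(0.5 * stats.chi2.sf(stat, df) + 0.5 * lower)


@dataclass
class VariancePartition:
    v_tot: float
    v_st: float
    v_fc: float
    v_sc: float
    v_noise: float

    @property
    def fractions(self) -> dict[str, float]:
        return {
            "segregating_trans": self.v_st / self.v_tot,
            "fixed_cis": self.v_fc / self.v_tot,
            "segregating_cis": self.v_sc / self.v_tot,
            "noise": self.v_noise / self.v_tot,
        }


def partition_variance(table: CountTable, fit: GlmmFit) -> VariancePartition:
    """Partition count variance into trans / fixed-cis / segregating-cis /
    noise components by telescoping mean squared prediction errors.

    ``V_noise`` uses the full prediction (all effects the fitted model
    carries); ``V_cis+noise`` uses fixed effects only; ``V_sc+noise`` adds
    the arm effects.  ``V_st = V_tot - V_cis+noise`` and the remaining
    components follow by differences, so the four fractions sum to one
    exactly.
    """
    d = fit._design
    if d is None:
        raise ValueError("fit lacks its design; refit with fit_glmm")
    key_cell = {
        (h, a): i for i, (h, a) in enumerate(zip(d.h, d.a))
    }
    obs_cell = np.array(
        [key_cell[(h, a)] for h, a in zip(table.hybrid, table.arm)], dtype=int
    )
    C = table.count.astype(float)
    v_tot = float(np.mean((C - C.mean()) ** 2))

    pred_fixed = fit.cell_means("fixed")[obs_cell]
    v_cis_noise = float(np.mean((C - pred_fixed) ** 2))
    pred_arm = fit.cell_means("arm")[obs_cell]
    v_sc_noise = float(np.mean((C - pred_arm) ** 2))
    pred_full = fit.cell_means("full")[obs_cell]
    v_noise = float(np.mean((C - pred_full) ** 2))

    return VariancePartition(
        v_tot=v_tot,
        v_st=v_tot - v_cis_noise,
        v_fc=v_cis_noise - v_sc_noise,
        v_sc=v_sc_noise - v_noise,
        v_noise=v_noise,
    )


def gtest_long_arms(
    events_on_arm: dict[str, Sequence[int]],
    totals: Sequence[int],
    n_arms_tested: int | None = None,
) -> pd.DataFrame:
    """Per-arm G-test of homogeneity of tLOH proportions across hybrids.

    ``events_on_arm[arm]`` holds the per-hybrid counts of terminal events on
    that arm; ``totals`` the per-hybrid genome-wide totals.  Hybrids with a
    zero total are excluded with a warning (degrees of freedom reduced).
    P-values are Bonferroni-adjusted by the number of arms tested.
    """
    totals = np.asarray(totals, dtype=float)
    if n_arms_tested is None:
        n_arms_tested = len(events_on_arm)
    rows = []
    for arm, on_arm in events_on_arm.items():
        on = np.asarray(on_arm, dtype=float)
        if len(on) != len(totals):
            raise ValueError("per-arm counts must align with totals")
        keep = totals > 0
        if not np.all(keep):
            logger.warning(
                "gtest_long_arms(%s): excluding %d hybrids with zero events",
                arm,
                int(np.sum(~keep)),
            )
        on_k = on[keep]
        tot_k = totals[keep]
        off_k = tot_k - on_k
        if np.any(off_k < 0):
            raise ValueError("on-arm counts exceed totals")
        table = np.vstack([on_k, off_k])
        col = table.sum(axis=0)
        row = table.sum(axis=1)
        expected = np.outer(row, col) / col.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(table > 0, table * np.log(table / expected), 0.0)
        g = 2.0 * float(terms.sum())
        df = len(tot_k) - 1
        p = float(stats.chi2.sf(g, df)) if df > 0 else 1.0
        rows.append((arm, g, df, p, min(1.0, p * n_arms_tested)))
    return pd.DataFrame(rows, columns=["arm", "G", "df", "p", "p_bonferroni"])
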