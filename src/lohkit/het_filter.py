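"""Beta-binomial allele-balance model and heterozygous-call filter.

At a true heterozygous site the count of reads supporting the second
parental allele is binomial(n, 1/2) under the simplest model; PCR and
mapping artifacts overdisperse it.  We model the count as beta-binomial
with ``alpha = beta`` so its variance is ``n/4 + rho*n*(n-1)`` with
``rho = 1/(8*beta + 4)``, fit ``rho`` across read-depth bins, and discard
heterozygous calls whose support falls outside the central 95% interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calls_io import Genotype
from .dual_reference import FamilyMatrix

__all__ = [
    "OverdispersionFit",
    "high_confidence_het_sites",
    "fit_overdispersion",
    "beta_binomial_ci",
    "filter_het_calls",
    "rho_from_beta",
]


def rho_from_beta(beta: float) -> float:
    """Excess-variance coefficient ``rho = 1/(8*beta + 4)``."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    return 1.0 / (8.0 * beta + 4.0)


@dataclass
class OverdispersionFit:
    """Result of fitting the depth-binned variance model."""

    rho: float
    beta: float
    bin_table: pd.DataFrame  # columns: n, n_calls, mean, var
    r2: float

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# rho={self.rho:.6g}\tbeta={self.beta:.6g}\tr2={self.r2:.6g}\n")
            self.bin_table.to_csv(fh, sep="\t", index=False)


def high_confidence_het_sites(
    families: list[FamilyMatrix],
    founder_min_frac: float = 15.0 / 16.0,
    endpoint_min_frac: float = 2.0 / 3.0,
) -> np.ndarray:
    """Boolean mask of markers heterozygous across nearly all samples.

    A marker qualifies when it is called heterozygous in at least
    ``ceil(founder_min_frac * n_founders)`` founders and at least
    ``ceil(endpoint_min_frac * n_endpoints)`` end-point clones, counting
    across all families (which must share a marker set).
    """
    if len(families) < 2:
        raise ValueError(
            "need at least 2 families; for a single family lower the founder "
            "threshold and call with the family repeated is not supported"
        )
    n_markers = len(families[0].markers)
    for fam in families[1:]:
        if len(fam.markers) != n_markers:
            raise ValueError("families must share a common marker set")

    founder_het = np.zeros(n_markers, dtype=int)
    n_founders = 0
    endpoint_het = np.zeros(n_markers, dtype=int)
    n_endpoints = 0
    for fam in families:
        fi = fam.founder_idx
        if fi is not None:
            founder_het += fam.genotypes[:, fi] == Genotype.HET
            n_founders += 1
        ep = fam.endpoint_indices
        endpoint_het += (fam.genotypes[:, ep] == Genotype.HET).sum(axis=1)
        n_endpoints += len(ep)
    if n_founders == 0:
        raise ValueError("no sequenced founders among the families")

    need_founders = math.ceil(founder_min_frac * n_founders)
    need_endpoints = math.ceil(endpoint_min_frac * n_endpoints)
    return (founder_het >= need_founders) & (endpoint_het >= need_endpoints)


def fit_overdispersion(
    depths: np.ndarray,
    p2_counts: np.ndarray,
    min_bin: int = 100,
) -> OverdispersionFit:
    """Fit ``sigma^2(n) = n/4 + rho*n*(n-1)`` over integer read-depth bins.

    Bins with fewer than ``min_bin`` calls are discarded.  ``rho`` is
    estimated by least squares weighted by bin call counts; ``beta`` is
    recovered as ``(1/rho - 4)/8`` (0 when the fit is at or below the
    binomial limit).  ``r2`` is the weighted fraction of variance-in-
    variance explained.
    """
    depths = np.asarray(depths, dtype=int)
    p2 = np.asarray(p2_counts, dtype=float)
    if depths.shape != p2.shape:
        raise ValueError("depths and counts must align")

    rows = []
    for n in np.unique(depths):
        sel = depths == n
        k = int(sel.sum())
        if k < min_bin:
            continue
        vals = p2[sel]
        rows.append((int(n), k, float(vals.mean()), float(vals.var(ddof=1))))
    if len(rows) < 3:
        raise ValueError(
            f"only {len(rows)} depth bins with >= {min_bin} calls; need >= 3"
        )
    tab = pd.DataFrame(rows, columns=["n", "n_calls", "mean", "var"])

    n = tab["n"].to_numpy(float)
    w = tab["n_calls"].to_numpy(float)
    y = tab["var"].to_numpy(float) - n / 4.0
    x = n * (n - 1.0)
    rho = float(np.sum(w * x * y) / np.sum(w * x * x))
    rho = max(rho, 0.0)
    beta = (1.0 / rho - 4.0) / 8.0 if rho > 0 else np.inf

    fitted = n / 4.0 + rho * x
    resid = tab["var"].to_numpy(float) - fitted
    tot = tab["var"].to_numpy(float) - np.average(tab["var"], weights=w)
    ss_res = float(np.sum(w * resid**2))
    ss_tot = float(np.sum(w * tot**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return OverdispersionFit(rho=rho, beta=beta, bin_table=tab, r2=r2)


def beta_binomial_ci(
    n: int, beta: float, level: float = 0.95, mode: str = "closest"
) -> tuple[int, int]:
    """Central inclusive interval of the symmetric beta-binomial.

    A discrete distribution admits no exact central interval, so the cut is
    a convention.  With ``mode="closest"`` (default) ``lo`` is the integer
    whose excluded lower-tail mass ``P(X < lo)`` is closest to
    ``(1-level)/2``, which makes the realized two-sided removal probability
    track ``1 - level`` on average across depths.  With ``mode="strict"``
    ``lo`` is the largest integer whose lower tail does not exceed
    ``(1-level)/2`` (guaranteed coverage of at least ``level``).  By the
    ``alpha = beta`` symmetry ``hi = n - lo``; endpoints lie inside the
    interval.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    tail = (1.0 - level) / 2.0
    if not np.isfinite(beta):
        cdf = stats.binom(n, 0.5).cdf(np.arange(-1, n + 1))
    else:
        cdf = stats.betabinom(n, beta, beta).cdf(np.arange(-1, n + 1))
    # cdf[k] = P(X <= k-1) = P(X < k)
    if mode == "closest":
        lo = int(np.argmin(np.abs(cdf - tail)))
    elif mode == "strict":
        lo = int(np.max(np.flatnonzero(cdf <= tail + 1e-12)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    lo = min(lo, n // 2)
    hi = n - lo
    return lo, hi


def filter_het_calls(
    genotypes: np.ndarray,
    depths: np.ndarray,
    p2_counts: np.ndarray,
    fit: OverdispersionFit | None = None,
    beta: float | None = None,
    level: float = 0.95,
) -> tuple[np.ndarray, int]:
    """Set implausibly unbalanced heterozygous calls to MISSING.

    Heterozygous calls whose second-parent read support falls outside the
    beta-binomial central interval for their depth are removed (set to
    MISSING, never re-assigned homozygous); homozygous and missing calls
    pass through untouched.  Idempotent.

    Returns the filtered genotype array and the number of removed calls.
    """
    if beta is None:
        if fit is None:
            raise ValueError("provide a fit or an explicit beta")
        beta = fit.beta
    g = np.asarray(genotypes, dtype=np.int8).copy()
    depths = np.asarray(depths, dtype=int)
    p2 = np.asarray(p2_counts, dtype=int)

    het = g == Genotype.HET
    if not het.any():
        return g, 0
    bounds: dict[int, tuple[int, int]] = {}
    for n in np.unique(depths[het]):
        if n < 1:
            bounds[int(n)] = (0, 0)
        else:
            bounds[int(n)] = beta_binomial_ci(int(n), beta, level)
    lo = np.zeros_like(depths)
    hi = np.zeros_like(depths)
    for n, (l, h) in bounds.items():
        sel = depths == n
        lo[sel] = l
        hi[sel] = h
    bad = het & ((p2 < lo) | (p2 > hi))
    g[bad] = Genotype.MISSING
    return g, int(bad.sum())
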