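"""Founder genotyping-error model and Homo-/Hetero-FDR estimators.

A family of mutation-accumulation lines shares the founder genome except
where a mutation or an LOH event hit a lineage, so a founder genotyping
error shows up as a mismatch between the founder call and the plurality of
its descendants.  The model scores a founder call against the observed
descendant configuration ``(K0, K1, K2)`` via posterior odds ratios built
from descendant-state transition probabilities ``p_ij`` (probability of
observing a descendant with ``j`` derived alleles given an ancestor with
``i``).

The precise two-stage form of ``p_ij`` used here is a documented modelling
assumption:

* stage 1 (true descendant state after the experiment): a heterozygous
  ancestor becomes homozygous on either side with probability
  ``(lam + mu) / 2`` each and stays heterozygous with ``1 - lam - mu``;
  a homozygous ancestor becomes heterozygous with probability ``mu``
  (LOH does not alter homozygous sites; double events are neglected);
* stage 2 (observation): a true heterozygote is called homozygous on each
  side with probability ``eps_hom`` (``2 * eps_hom`` total) and
  heterozygous with ``1 - 2 * eps_hom``; a true homozygote is called
  heterozygous with probability ``eps_het``, the opposite homozygote with
  probability 0, and correctly otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .calls_io import Genotype
from .dual_reference import FamilyMatrix

__all__ = [
    "ErrorModelParams",
    "DescendantConfig",
    "transition_probs",
    "odds_false_hom",
    "odds_false_het",
    "f_from_observed",
    "estimate_fdrs",
    "FdrEstimate",
    "lambda_from_rate",
    "permutation_pvalue",
]


def lambda_from_rate(rate_per_bp_gen: float, generations: float) -> float:
    """Per-site conversion probability over the experiment from a per-bp
    per-generation rate, e.g. ``1.6e-4 * 800 = 0.128``."""
    lam = rate_per_bp_gen * generations
    if not 0 <= lam <= 1:
        raise ValueError(f"lambda = {lam} outside [0, 1]")
    return lam


@dataclass(frozen=True)
class ErrorModelParams:
    """The five probabilities of the founder-error model."""

    mu: float
    lam: float
    f: float
    eps_hom: float
    eps_het: float

    def __post_init__(self) -> None:
        for name in ("mu", "lam", "f", "eps_hom", "eps_het"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.mu + self.lam > 1.0:
            raise ValueError("mu + lam must not exceed 1")
        if 2 * self.eps_hom > 1.0:
            raise ValueError("2*eps_hom must not exceed 1")


@dataclass(frozen=True)
class DescendantConfig:
    """Observed descendant genotype counts at one site.

    ``K0``: called homozygous for the ancestral allele, ``K1``: called
    heterozygous, ``K2``: called homozygous for the derived allele.
    """

    K0: int
    K1: int
    K2: int

    def __post_init__(self) -> None:
        if min(self.K0, self.K1, self.K2) < 0:
            raise ValueError("descendant counts must be non-negative")

    @property
    def n(self) -> int:
        return self.K0 + self.K1 + self.K2


def transition_probs(params: ErrorModelParams) -> np.ndarray:
    """The 2x3 matrix ``p[i, j]`` of descendant observation probabilities.

    Row ``i = 0``: ancestor homozygous (zero derived alleles); row
    ``i = 1``: ancestor heterozygous.  Columns are the observed descendant
    state ``j`` in {0: hom ancestral, 1: het, 2: hom derived}.  Rows sum to
    one exactly (law of total probability).
    """
    mu, lam = params.mu, params.lam
    e1, e2 = params.eps_hom, params.eps_het
    # stage-1 state distributions
    # ancestor hom: stays hom(j=0) w.p. 1-mu, flips to het w.p. mu
    # ancestor het: hom either side w.p. (lam+mu)/2, stays het 1-lam-mu
    conv = (lam + mu) / 2.0
    stay = 1.0 - lam - mu
    # stage-2 observation kernel rows: true state -> called state
    obs_hom = np.array([1.0 - e2, e2, 0.0])  # true hom-ancestral
    obs_het = np.array([e1, 1.0 - 2.0 * e1, e1])  # true het
    obs_hom2 = np.array([0.0, e2, 1.0 - e2])  # true hom-derived
    p0 = (1.0 - mu) * obs_hom + mu * obs_het
    p1 = conv * obs_hom + stay * obs_het + conv * obs_hom2
    return np.vstack([p0, p1])


def _log_odds(
    prior_log: float, probs: np.ndarray, config: DescendantConfig, numer_row: int
) -> float:
    """log posterior odds with the data term in log space.

    ``numer_row`` indexes the hypothesis in the numerator; returns +inf when
    a required numerator probability is zero alongside a nonzero count with
    a zero denominator (documented behaviour, never NaN).
    """
    denom_row = 1 - numer_row
    ks = np.array([config.K0, config.K1, config.K2], dtype=float)
    log_r = prior_log
    with np.errstate(divide="ignore"):
        ln_num = np.log(probs[numer_row])
        ln_den = np.log(probs[denom_row])
    for j in range(3):
        if ks[j] == 0:
            continue
        if probs[denom_row, j] == 0.0 and probs[numer_row, j] > 0.0:
            return np.inf
        if probs[numer_row, j] == 0.0:
            return -np.inf
        log_r += ks[j] * (ln_num[j] - ln_den[j])
    return log_r


def odds_false_hom(params: ErrorModelParams, config: DescendantConfig) -> float:
    """Posterior odds that a founder called homozygous is truly heterozygous.

    ``R = [eps_hom/(1-eps_het)] * [(1-f)/f] * prod_j (p_1j/p_0j)^K_j``.
    """
    if params.f == 0.0:
        return np.inf
    probs = transition_probs(params)
    with np.errstate(divide="ignore"):
        prior = (
            np.log(params.eps_hom)
            - np.log1p(-params.eps_het)
            + np.log1p(-params.f)
            - np.log(params.f)
        )
    return float(np.exp(_log_odds(prior, probs, config, numer_row=1)))


def odds_false_het(params: ErrorModelParams, config: DescendantConfig) -> float:
    """Posterior odds that a founder called heterozygous is truly homozygous.

    ``R = [eps_het/(1-2*eps_hom)] * [f/(1-f)] * prod_j (p_0j/p_1j)^K_j``.
    """
    if params.f == 1.0:
        return np.inf
    probs = transition_probs(params)
    with np.errstate(divide="ignore"):
        prior = (
            np.log(params.eps_het)
            - np.log1p(-2.0 * params.eps_hom)
            + np.log(params.f)
            - np.log1p(-params.f)
        )
    return float(np.exp(_log_odds(prior, probs, config, numer_row=0)))


def f_from_observed(f_obs: float, eps_hom: float, eps_het: float) -> float:
    """Invert ``f_obs = f (1 - eps_het) + (1 - f) eps_hom`` for ``f``.

    Raises when the implied ``f`` falls outside [0, 1], naming the violated
    feasibility bound (``eps_hom <= f_obs`` and ``eps_het <= 1 - f_obs``).
    """
    denom = 1.0 - eps_hom - eps_het
    if denom <= 0:
        raise ValueError("eps_hom + eps_het must be < 1")
    f = (f_obs - eps_hom) / denom
    if f < 0:
        raise ValueError(
            f"infeasible: eps_hom = {eps_hom} exceeds f_obs = {f_obs} "
            "(requires eps_hom <= f_obs)"
        )
    if f > 1:
        raise ValueError(
            f"infeasible: eps_het = {eps_het} exceeds 1 - f_obs = {1 - f_obs} "
            "(requires eps_het <= 1 - f_obs)"
        )
    return f


@dataclass
class FdrEstimate:
    """Pooled and per-family false discovery rate for one error direction."""

    n_false: int
    n_eligible: int
    per_family: list[tuple[int, int]]

    @property
    def pooled(self) -> float | None:
        if self.n_eligible == 0:
            return None
        return self.n_false / self.n_eligible

    @property
    def per_family_rates(self) -> list[float | None]:
        return [None if n == 0 else k / n for k, n in self.per_family]


def estimate_fdrs(
    families: Sequence[FamilyMatrix],
    min_descendants: int = 6,
) -> tuple[FdrEstimate, FdrEstimate, list[dict]]:
    """Estimate Hetero-FDR and Homo-FDR from founder/descendant discordance.

    A founder-homozygous site is labeled *false homozygous* when at least
    ``min_descendants`` descendants are genotyped there and **all** of them
    are called heterozygous; a founder-heterozygous site is labeled *false
    heterozygous* when at least ``min_descendants`` descendants are
    genotyped and **all** are homozygous for the same allele.  Denominators
    count founder sites of the matching state with enough genotyped
    descendants.

    Returns ``(hetero_fdr, homo_fdr, labels)`` where ``labels`` is a list of
    dicts (family, chrom, pos, label).
    """
    het_pf: list[tuple[int, int]] = []
    hom_pf: list[tuple[int, int]] = []
    labels: list[dict] = []
    for fam_i, fam in enumerate(families):
        fi = fam.founder_idx
        if fi is None:
            raise ValueError("estimate_fdrs requires a sequenced founder")
        ep = fam.endpoint_indices
        g = fam.genotypes
        founder = g[:, fi]
        desc = g[:, ep]
        genotyped = desc != Genotype.MISSING
        n_geno = genotyped.sum(axis=1)
        eligible = n_geno >= min_descendants

        is_hom = (founder == Genotype.HOM_P1) | (founder == Genotype.HOM_P2)
        is_het = founder == Genotype.HET

        all_het = np.all((desc == Genotype.HET) | ~genotyped, axis=1) & (n_geno > 0)
        false_hom = eligible & is_hom & all_het

        all_p1 = np.all((desc == Genotype.HOM_P1) | ~genotyped, axis=1) & (n_geno > 0)
        all_p2 = np.all((desc == Genotype.HOM_P2) | ~genotyped, axis=1) & (n_geno > 0)
        false_het = eligible & is_het & (all_p1 | all_p2)

        hom_pf.append((int(false_hom.sum()), int((eligible & is_hom).sum())))
        het_pf.append((int(false_het.sum()), int((eligible & is_het).sum())))

        fam_name = fam.founder or f"family{fam_i}"
        for kind, mask in (("false_homozygous", false_hom), ("false_heterozygous", false_het)):
            idx = np.flatnonzero(mask)
            for i in idx:
                row = fam.markers.table.iloc[i]
                labels.append(
                    {
                        "family": fam_name,
                        "chrom": row["chrom"],
                        "pos": int(row["pos"]),
                        "label": kind,
                    }
                )

    hetero = FdrEstimate(
        n_false=sum(k for k, _ in het_pf),
        n_eligible=sum(n for _, n in het_pf),
        per_family=het_pf,
    )
    homo = FdrEstimate(
        n_false=sum(k for k, _ in hom_pf),
        n_eligible=sum(n for _, n in hom_pf),
        per_family=hom_pf,
    )
    return hetero, homo, labels


def permutation_pvalue(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-sided permutation test for a difference in per-family means.

    Shuffles family labels between the two conditions and compares the
    absolute difference of group means against its permutation
    distribution.  Used to compare per-family FDRs (or event counts)
    between two genotyping procedures.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    observed = abs(a.mean() - b.mean())
    n_a = len(a)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if abs(pooled[:n_a].mean() - pooled[n_a:].mean()) >= observed - 1e-15:
            hits += 1
    return (hits + 1) / (n_perm + 1)
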