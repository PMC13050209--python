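"""Synthetic mutation-accumulation experiments with full truth bookkeeping.

Simulation starts at the call-set level (no reads are simulated): markers
are placed on a genome, LOH events drawn per arm from the same generative
model the inference assumes (Poisson counts through the stitched links for
interstitial events, Bernoulli occurrence for terminal events), genotyping
errors and beta-binomial read counts injected, and two per-reference call
sets emitted together with an identity chain (the two parental references
differ by substitutions only) and telomere masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calls_io import ChainMap, GenomeMeta, Genotype, telomere_mask
from .dual_reference import FamilyMatrix, MarkerSet
from .variance_model import (
    BernoulliStitchLink,
    CountTable,
    IdentityLogLink,
)

__all__ = [
    "SimGenome",
    "HybridConfig",
    "SimConfig",
    "SimTruth",
    "SimCallSet",
    "SimResult",
    "simulate_experiment",
    "inject_reference_bias",
    "simulate_count_table",
    "default_genome",
]


@dataclass(frozen=True)
class SimGenome:
    chrom_lengths: dict[str, int]
    centromeres: dict[str, int]

    def arms(self) -> list[tuple[str, str, int, int]]:
        """(chrom, arm name, start, end) half-open; left arm ends at the
        centromere."""
        out = []
        for chrom, L in self.chrom_lengths.items():
            cen = self.centromeres[chrom]
            out.append((chrom, f"{chrom}-l", 1, cen))
            out.append((chrom, f"{chrom}-r", cen, L + 1))
        return out

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())


def default_genome(n_chroms: int = 4, chrom_bp: int = 600_000) -> SimGenome:
    """A small yeast-like genome for tests: equal chromosomes, centromere
    at 40% of the length."""
    lengths = {f"chr{i + 1:02d}": chrom_bp for i in range(n_chroms)}
    cens = {c: int(0.4 * L) for c, L in lengths.items()}
    return SimGenome(chrom_lengths=lengths, centromeres=cens)


@dataclass
class HybridConfig:
    """Per-hybrid design and generative coefficients.

    Rates follow the linear model ``lambda_a = mu + alpha * L_a(Mb) +
    beta_a + gamma_a`` (per generation) with the arm and hybrid-by-arm
    deviations drawn from zero-mean normals; expected counts go through the
    stitched links.  Explicit per-arm rates override the linear model.
    """

    name: str
    n_clones: int = 10
    generations: float = 800.0
    iloh_mu: float = 2e-5
    iloh_alpha: float = 2e-4  # per Mb per generation
    iloh_sigma_fc: float = 0.0
    iloh_sigma_sc: float = 0.0
    tloh_mu: float = 5e-6
    tloh_alpha: float = 5e-5
    tloh_sigma_fc: float = 0.0
    tloh_sigma_sc: float = 0.0
    iloh_rates: dict[str, float] | None = None  # per-arm overrides
    tloh_rates: dict[str, float] | None = None
    founder_sequenced: bool = True


@dataclass
class SimConfig:
    genome: SimGenome
    hybrids: list[HybridConfig]
    seed: int
    n_markers: int = 2000
    iloh_len_median: float = 2000.0
    iloh_len_sigma: float = 1.2  # log-scale SD of the log-normal lengths
    eps_hom: float = 0.0  # per-side false-homozygote call probability
    eps_het: float = 0.0
    mean_depth: float = 60.0
    read_beta: float = 59.0  # beta-binomial shape at heterozygous sites
    hom_error_read_rate: float = 0.003
    delta_iloh: float = 0.01
    delta_tloh: float = 0.03

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("eps_hom", "eps_het"):
            v = getattr(self, name)
            if not 0 <= v <= 0.5:
                raise ValueError(f"{name} must lie in [0, 0.5]")
        if not self.hybrids:
            raise ValueError("at least one hybrid required")


@dataclass
class SimTruth:
    """Ground truth for one simulated experiment."""

    events: pd.DataFrame  # hybrid, clone, chrom, arm, start, end, type, homolog
    genotypes: dict[str, np.ndarray]  # hybrid -> markers x clones true states
    error_positions: pd.DataFrame  # hybrid, clone, ref, marker_idx, kind
    per_arm_lambda: pd.DataFrame  # hybrid, arm, iloh_rate, tloh_rate
    per_arm_counts: pd.DataFrame  # hybrid, clone, arm, iloh_count, tloh_count


@dataclass
class SimCallSet:
    """One reference's calls for a whole family, in parental-allele space."""

    markers: MarkerSet
    clones: list[str]
    genotypes: np.ndarray  # int8 markers x clones
    gq: np.ndarray
    depth: np.ndarray
    p2_reads: np.ndarray
    founder: str | None = None

    def to_family_matrix(self) -> FamilyMatrix:
        return FamilyMatrix(
            markers=self.markers,
            clones=list(self.clones),
            genotypes=self.genotypes.copy(),
            gq=self.gq.copy(),
            founder=self.founder,
        )


@dataclass
class SimResult:
    config: SimConfig
    markers: MarkerSet
    meta: GenomeMeta
    chain: ChainMap
    truth: SimTruth
    call_sets: dict[str, tuple[SimCallSet, SimCallSet]]  # hybrid -> (ref1, ref2)


_BASES = np.array(list("ACGT"))


def _place_markers(genome: SimGenome, n: int, rng) -> pd.DataFrame:
    lengths = np.array(list(genome.chrom_lengths.values()), dtype=float)
    chroms = list(genome.chrom_lengths)
    per = rng.multinomial(n, lengths / lengths.sum())
    rows = []
    for chrom, k, L in zip(chroms, per, lengths):
        pos = np.sort(rng.choice(np.arange(1, int(L) + 1), size=min(k, int(L)), replace=False))
        b1 = rng.integers(0, 4, size=len(pos))
        b2 = (b1 + rng.integers(1, 4, size=len(pos))) % 4
        for p, a, b in zip(pos, b1, b2):
            rows.append((chrom, int(p), _BASES[a], _BASES[b]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "p1_allele", "p2_allele"])


def _arm_lambdas(hyb: HybridConfig, genome: SimGenome, kind: str, rng) -> dict[str, float]:
    override = hyb.iloh_rates if kind == "iloh" else hyb.tloh_rates
    arms = genome.arms()
    if override is not None:
        return {a: override[a] for _, a, _, _ in arms}
    mu = getattr(hyb, f"{kind}_mu")
    alpha = getattr(hyb, f"{kind}_alpha")
    s_fc = getattr(hyb, f"{kind}_sigma_fc")
    s_sc = getattr(hyb, f"{kind}_sigma_sc")
    out = {}
    for _, arm, s, e in arms:
        L_mb = (e - s) / 1e6
        lam = mu + alpha * L_mb
        if s_fc > 0:
            lam += rng.normal(0.0, s_fc)
        if s_sc > 0:
            lam += rng.normal(0.0, s_sc)
        out[arm] = lam
    return out


def simulate_experiment(config: SimConfig) -> SimResult:
    """Run the full generative model; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    genome = config.genome
    markers = MarkerSet(_place_markers(genome, config.n_markers, rng))
    n_mark = len(markers)
    chrom_of = markers.table["chrom"].to_numpy()
    pos_of = markers.table["pos"].to_numpy()

    meta = GenomeMeta(
        chrom_lengths=dict(genome.chrom_lengths),
        centromeres=dict(genome.centromeres),
    )
    meta.add_masks(telomere_mask(genome.chrom_lengths, 7500))
    chain = ChainMap.identity(genome.chrom_lengths)

    link_i = IdentityLogLink(config.delta_iloh)
    link_t = BernoulliStitchLink(config.delta_tloh)

    ev_rows, lam_rows, cnt_rows, err_rows = [], [], [], []
    genotypes_true: dict[str, np.ndarray] = {}
    call_sets: dict[str, tuple[SimCallSet, SimCallSet]] = {}

    for hyb in config.hybrids:
        lam_i = _arm_lambdas(hyb, genome, "iloh", rng)
        lam_t = _arm_lambdas(hyb, genome, "tloh", rng)
        for _, arm, _, _ in genome.arms():
            lam_rows.append((hyb.name, arm, lam_i[arm], lam_t[arm]))

        clones = [f"{hyb.name}_c{i:03d}" for i in range(hyb.n_clones)]
        founder = f"{hyb.name}_founder" if hyb.founder_sequenced else None
        all_samples = ([founder] if founder else []) + clones
        G = np.full((n_mark, len(all_samples)), int(Genotype.HET), dtype=np.int8)

        offset = 1 if founder else 0
        for ci, clone in enumerate(clones):
            col = offset + ci
            for chrom, arm, a_start, a_end in genome.arms():
                L_arm = a_end - a_start
                xi_i = lam_i[arm] * hyb.generations
                k = rng.poisson(link_i.f(np.array([xi_i]))[0])
                cnt_i = int(k)
                sel_chrom = chrom_of == chrom
                for _ in range(k):
                    length = max(
                        1,
                        int(
                            rng.lognormal(
                                np.log(config.iloh_len_median), config.iloh_len_sigma
                            )
                        ),
                    )
                    start = int(rng.integers(a_start, a_end))
                    end = min(start + length - 1, a_end - 1)
                    homolog = int(rng.integers(0, 2)) * 2  # HOM_P1 or HOM_P2
                    hit = sel_chrom & (pos_of >= start) & (pos_of <= end)
                    G[hit, col] = homolog
                    ev_rows.append(
                        (hyb.name, clone, chrom, arm, start, end, "interstitial",
                         "P1" if homolog == 0 else "P2")
                    )
                xi_t = lam_t[arm] * hyb.generations
                p_t = link_t.f(np.array([xi_t]))[0]
                cnt_t = int(rng.random() < p_t)
                if cnt_t:
                    bp = int(rng.integers(a_start, a_end))
                    homolog = int(rng.integers(0, 2)) * 2
                    left_arm = arm.endswith("-l")
                    if left_arm:
                        s_ev, e_ev = 1, bp
                    else:
                        s_ev, e_ev = bp, genome.chrom_lengths[chrom]
                    hit = sel_chrom & (pos_of >= s_ev) & (pos_of <= e_ev)
                    G[hit, col] = homolog
                    ev_rows.append(
                        (hyb.name, clone, chrom, arm, s_ev, e_ev, "terminal",
                         "P1" if homolog == 0 else "P2")
                    )
                cnt_rows.append((hyb.name, clone, arm, cnt_i, cnt_t))

        genotypes_true[hyb.name] = G

        # reads reflect the true genotype; depth is Poisson around the mean
        depth = rng.poisson(config.mean_depth, size=G.shape).clip(min=2)
        p_het = rng.beta(config.read_beta, config.read_beta, size=G.shape)
        p2 = np.where(
            G == Genotype.HET,
            rng.binomial(depth, p_het),
            np.where(
                G == Genotype.HOM_P2,
                depth - rng.binomial(depth, config.hom_error_read_rate),
                rng.binomial(depth, config.hom_error_read_rate),
            ),
        )

        refs = []
        for ref in (1, 2):
            called = G.copy()
            if config.eps_hom > 0 or config.eps_het > 0:
                u = rng.random(G.shape)
                het = G == Genotype.HET
                to_p1 = het & (u < config.eps_hom)
                to_p2 = het & (u >= config.eps_hom) & (u < 2 * config.eps_hom)
                hom = (G == Genotype.HOM_P1) | (G == Genotype.HOM_P2)
                to_het = hom & (u < config.eps_het)
                called[to_p1] = Genotype.HOM_P1
                called[to_p2] = Genotype.HOM_P2
                called[to_het] = Genotype.HET
                for kind, mask in (
                    ("false_hom_p1", to_p1),
                    ("false_hom_p2", to_p2),
                    ("false_het", to_het),
                ):
                    mi, cj = np.nonzero(mask)
                    for i, j in zip(mi, cj):
                        err_rows.append((hyb.name, all_samples[j], ref, int(i), kind))
            gq = np.full(G.shape, 99.0)
            refs.append(
                SimCallSet(
                    markers=markers,
                    clones=list(all_samples),
                    genotypes=called,
                    gq=gq,
                    depth=depth,
                    p2_reads=p2,
                    founder=founder,
                )
            )
        call_sets[hyb.name] = (refs[0], refs[1])

    truth = SimTruth(
        events=pd.DataFrame(
            ev_rows,
            columns=["hybrid", "clone", "chrom", "arm", "start", "end", "type", "homolog"],
        ),
        genotypes=genotypes_true,
        error_positions=pd.DataFrame(
            err_rows, columns=["hybrid", "clone", "ref", "marker_idx", "kind"]
        ),
        per_arm_lambda=pd.DataFrame(
            lam_rows, columns=["hybrid", "arm", "iloh_rate", "tloh_rate"]
        ),
        per_arm_counts=pd.DataFrame(
            cnt_rows, columns=["hybrid", "clone", "arm", "iloh_count", "tloh_count"]
        ),
    )
    return SimResult(
        config=config,
        markers=markers,
        meta=meta,
        chain=chain,
        truth=truth,
        call_sets=call_sets,
    )


def inject_reference_bias(
    call_set: SimCallSet,
    bias_marker_idx: np.ndarray,
    strength: float,
    toward: str = "P1",
    seed: int = 0,
    biased_gq: float = 99.0,
) -> SimCallSet:
    """Skew heterozygous calls toward one reference at selected markers.

    At the given marker rows, each heterozygous call flips to the homozygous
    state of the ``toward`` parent with probability ``strength``; allele
    depths are skewed accordingly and the call's GQ set to ``biased_gq``.
    ``strength = 0`` is the identity.  Only the call set belonging to the
    biased reference should be passed through this function.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must be in [0, 1]")
    if toward not in ("P1", "P2"):
        raise ValueError("toward must be 'P1' or 'P2'")
    if strength == 0.0:
        return call_set
    rng = np.random.default_rng(seed)
    g = call_set.genotypes.copy()
    gq = call_set.gq.copy()
    p2 = call_set.p2_reads.copy()
    target = Genotype.HOM_P1 if toward == "P1" else Genotype.HOM_P2
    rows = np.asarray(bias_marker_idx, dtype=int)
    sub = g[rows, :]
    flip = (sub == Genotype.HET) & (rng.random(sub.shape) < strength)
    sub = np.where(flip, np.int8(target), sub)
    g[rows, :] = sub
    sub_gq = gq[rows, :]
    sub_gq[flip] = biased_gq
    gq[rows, :] = sub_gq
    sub_p2 = p2[rows, :]
    d = call_set.depth[rows, :]
    sub_p2[flip] = 0 if toward == "P1" else d[flip]
    p2[rows, :] = sub_p2
    return replace(call_set, genotypes=g, gq=gq, p2_reads=p2)


def simulate_count_table(
    n_hybrids: int,
    n_arms: int,
    n_clones: int,
    generations: float,
    mu: float,
    alpha: np.ndarray | float,
    sigma_fc: float,
    sigma_sc: float,
    family: str,
    seed: int,
    arm_bp: np.ndarray | None = None,
    delta: float | None = None,
) -> tuple[CountTable, dict]:
    """Draw per-arm counts directly from the linear rate model.

    Returns the table and a truth dict with the drawn coefficients; used by
    the variance-model calibration loops where genome placement is
    irrelevant.
    """
    rng = np.random.default_rng(seed)
    if delta is None:
        delta = 0.01 if family == "poisson_iloh" else 0.03
    link = IdentityLogLink(delta) if family == "poisson_iloh" else BernoulliStitchLink(delta)
    if arm_bp is None:
        arm_bp = rng.uniform(1e5, 1.1e6, n_arms)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (n_hybrids,)).copy()
    L = arm_bp / 1e6
    beta = rng.normal(0.0, sigma_fc, n_arms) if sigma_fc > 0 else np.zeros(n_arms)
    gamma = (
        rng.normal(0.0, sigma_sc, (n_hybrids, n_arms))
        if sigma_sc > 0
        else np.zeros((n_hybrids, n_arms))
    )
    lam = mu + alpha[:, None] * L[None, :] + beta[None, :] + gamma
    m = link.f(lam * generations)
    rows = []
    for h in range(n_hybrids):
        if family == "poisson_iloh":
            C = rng.poisson(m[h], size=(n_clones, n_arms))
        else:
            C = (rng.random((n_clones, n_arms)) < m[h]).astype(int)
        for c in range(n_clones):
            for a in range(n_arms):
                rows.append(
                    (f"h{h:02d}", c, f"a{a:02d}", int(C[c, a]), arm_bp[a], generations)
                )
    table = CountTable.from_frame(
        pd.DataFrame(
            rows, columns=["hybrid", "clone", "arm", "count", "arm_bp", "generations"]
        )
    )
    truth = {
        "mu": mu,
        "alpha": alpha,
        "beta": beta,
        "gamma": gamma,
        "lambda": lam,
        "mean": m,
    }
    return table, truth
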