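"""Ancestral marker construction and reference-symmetric call reconciliation.

The central design goal of the dual-reference route is symmetry: every
operation here is invariant under swapping the two parental call sets
(with genotype labels re-oriented accordingly), which removes the
systematic bias toward the reference homolog that a single-reference
pipeline produces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calls_io import Genotype, SiteCall

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerSet",
    "FamilyMatrix",
    "potential_markers",
    "reconcile_calls",
    "reconcile_matrices",
    "final_markers",
    "detect_aneuploidy",
    "AneuploidyReport",
]


@dataclass
class MarkerSet:
    """Ordered ancestrally heterozygous marker positions with parental alleles.

    ``table`` has columns ``chrom, pos, p1_allele, p2_allele`` sorted by
    (chrom, pos) with strictly increasing positions per chromosome.
    """

    table: pd.DataFrame
    provenance: str = "potential"

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "p1_allele", "p2_allele"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"marker table must have columns {sorted(required)}")
        t = self.table.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
            drop=True
        )
        dup = t.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("duplicate marker positions")
        if (t["p1_allele"] == t["p2_allele"]).any():
            raise ValueError("marker with identical parental alleles")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    def positions(self, chrom: str) -> np.ndarray:
        return self.table.loc[self.table["chrom"] == chrom, "pos"].to_numpy()

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str, provenance: str = "potential") -> "MarkerSet":
        return cls(pd.read_csv(path, sep="\t"), provenance=provenance)


@dataclass
class FamilyMatrix:
    """Markers x clones genotype-state matrix for one family.

    ``genotypes`` and ``gq`` are ``(n_markers, n_clones)`` arrays; the
    founder column, when sequenced, is identified by ``founder`` naming one
    of ``clones``.
    """

    markers: MarkerSet
    clones: list[str]
    genotypes: np.ndarray  # int8, Genotype values
    gq: np.ndarray  # float
    founder: str | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.gq = np.asarray(self.gq, dtype=float)
        n_m, n_c = self.genotypes.shape
        if n_m != len(self.markers) or n_c != len(self.clones):
            raise ValueError("genotype matrix shape mismatch")
        if self.gq.shape != self.genotypes.shape:
            raise ValueError("gq matrix shape mismatch")
        if self.founder is not None and self.founder not in self.clones:
            raise ValueError(f"founder {self.founder!r} not among clones")

    @property
    def founder_idx(self) -> int | None:
        return None if self.founder is None else self.clones.index(self.founder)

    @property
    def endpoint_indices(self) -> list[int]:
        fi = self.founder_idx
        return [i for i in range(len(self.clones)) if i != fi]

    def subset_markers(self, mask: np.ndarray) -> "FamilyMatrix":
        return FamilyMatrix(
            markers=MarkerSet(
                self.markers.table.loc[mask].reset_index(drop=True),
                provenance=self.markers.provenance,
            ),
            clones=list(self.clones),
            genotypes=self.genotypes[mask],
            gq=self.gq[mask],
            founder=self.founder,
        )


def potential_markers(
    variants_p1: pd.DataFrame, variants_p2: pd.DataFrame
) -> MarkerSet:
    """Symmetric difference of the two parental variant sets.

    Each input lists positions where that parent differs from the common
    reference, with columns ``chrom, pos, ref, alt``.  Positions present in
    both sets are excluded (the two parents agree against the reference
    there, so the hybrid cannot be heterozygous); conflicting allele pairs
    at shared positions are logged before exclusion.
    """
    for df, name in ((variants_p1, "P1"), (variants_p2, "P2")):
        if not {"chrom", "pos", "ref", "alt"}.issubset(df.columns):
            raise ValueError(f"{name} variant table needs chrom, pos, ref, alt")
    k1 = set(zip(variants_p1["chrom"], variants_p1["pos"]))
    k2 = set(zip(variants_p2["chrom"], variants_p2["pos"]))
    shared = k1 & k2
    if shared:
        a1 = {
            (c, p): (r, a)
            for c, p, r, a in variants_p1[["chrom", "pos", "ref", "alt"]].itertuples(
                index=False
            )
        }
        a2 = {
            (c, p): (r, a)
            for c, p, r, a in variants_p2[["chrom", "pos", "ref", "alt"]].itertuples(
                index=False
            )
        }
        n_conflict = sum(1 for k in shared if a1[k] != a2[k])
        if n_conflict:
            logger.info(
                "potential_markers: %d shared positions with conflicting alleles "
                "excluded along with %d concordant shared positions",
                n_conflict,
                len(shared) - n_conflict,
            )

    only1 = variants_p1[
        [(c, p) not in shared for c, p in zip(variants_p1["chrom"], variants_p1["pos"])]
    ]
    only2 = variants_p2[
        [(c, p) not in shared for c, p in zip(variants_p2["chrom"], variants_p2["pos"])]
    ]
    # at a P1-only variant, P1 carries alt and P2 the reference base
    rows = pd.concat(
        [
            pd.DataFrame(
                {
                    "chrom": only1["chrom"],
                    "pos": only1["pos"],
                    "p1_allele": only1["alt"],
                    "p2_allele": only1["ref"],
                }
            ),
            pd.DataFrame(
                {
                    "chrom": only2["chrom"],
                    "pos": only2["pos"],
                    "p1_allele": only2["ref"],
                    "p2_allele": only2["alt"],
                }
            ),
        ],
        ignore_index=True,
    )
    return MarkerSet(rows, provenance="potential")


def reconcile_calls(
    call_ref1: SiteCall | None,
    call_ref2: SiteCall | None,
    gq_min: float = 50.0,
    gq_delta: float = 30.0,
) -> Genotype | None:
    """Reconcile one marker's two per-reference calls into a final genotype.

    Both calls must already be expressed in parental-allele space.  Returns
    the final :class:`~lohkit.calls_io.Genotype` or ``None`` for DISCARD.

    Rules, applied in order:

    1. either call missing, or both GQ below ``gq_min`` -> discard;
    2. genotypes agree (and at least one GQ passes) -> that genotype;
    3. genotypes disagree and ``|dGQ| >= gq_delta`` -> higher-GQ call;
    4. genotypes disagree and ``|dGQ| < gq_delta`` -> discard.
    """
    if call_ref1 is None or call_ref2 is None:
        return None
    if call_ref1.genotype == Genotype.MISSING or call_ref2.genotype == Genotype.MISSING:
        return None
    if call_ref1.alleles != call_ref2.alleles:
        raise ValueError(
            f"inconsistent allele spaces: {call_ref1.alleles} vs {call_ref2.alleles}"
        )
    g = _reconcile_arrays(
        np.array([int(call_ref1.genotype)], dtype=np.int8),
        np.array([call_ref1.gq]),
        np.array([int(call_ref2.genotype)], dtype=np.int8),
        np.array([call_ref2.gq]),
        gq_min,
        gq_delta,
    )[0][0]
    return None if g == int(Genotype.MISSING) else Genotype(g)


def _reconcile_arrays(
    gt1: np.ndarray,
    gq1: np.ndarray,
    gt2: np.ndarray,
    gq2: np.ndarray,
    gq_min: float,
    gq_delta: float,
) -> tuple[np.ndarray, dict[str, int]]:
    """Vectorized reconciliation; MISSING output encodes DISCARD."""
    gq1 = np.where(np.isnan(gq1), 0.0, gq1)
    gq2 = np.where(np.isnan(gq2), 0.0, gq2)
    missing = (gt1 == Genotype.MISSING) | (gt2 == Genotype.MISSING)
    low = (gq1 < gq_min) & (gq2 < gq_min)
    agree = gt1 == gt2
    delta = np.abs(gq1 - gq2)
    pick1 = gq1 >= gq2

    out = np.full(gt1.shape, int(Genotype.MISSING), dtype=np.int8)
    ok = ~missing & ~low
    out[ok & agree] = gt1[ok & agree]
    resolved = ok & ~agree & (delta >= gq_delta)
    out[resolved & pick1] = gt1[resolved & pick1]
    out[resolved & ~pick1] = gt2[resolved & ~pick1]
    counts = {
        "missing": int(np.sum(missing)),
        "both_low_gq": int(np.sum(~missing & low)),
        "agree": int(np.sum(ok & agree)),
        "resolved_by_gq": int(np.sum(resolved)),
        "discordant_discard": int(np.sum(ok & ~agree & (delta < gq_delta))),
    }
    return out, counts


def reconcile_matrices(
    gt1: np.ndarray,
    gq1: np.ndarray,
    gt2: np.ndarray,
    gq2: np.ndarray,
    gq_min: float = 50.0,
    gq_delta: float = 30.0,
) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Reconcile whole genotype/GQ matrices from the two references.

    Returns the final genotype matrix, a GQ matrix (the max of the two GQs
    where a call was emitted, NaN where discarded) and rule-branch counts.
    """
    gt1 = np.asarray(gt1, dtype=np.int8)
    gt2 = np.asarray(gt2, dtype=np.int8)
    out, counts = _reconcile_arrays(
        gt1.ravel(),
        np.asarray(gq1, float).ravel(),
        gt2.ravel(),
        np.asarray(gq2, float).ravel(),
        gq_min,
        gq_delta,
    )
    out = out.reshape(gt1.shape)
    gq = np.fmax(np.asarray(gq1, float), np.asarray(gq2, float))
    gq = np.where(out == int(Genotype.MISSING), np.nan, gq)
    return out, gq, counts


def final_markers(
    potential: MarkerSet,
    family: FamilyMatrix,
    min_desc_with_founder: int = 3,
    min_desc_without: int = 4,
) -> MarkerSet:
    """Restrict potential markers to high-confidence ancestrally het markers.

    With a sequenced founder a marker is retained when the founder is called
    heterozygous and at least ``min_desc_with_founder`` end-point clones are
    heterozygous; without a founder at least ``min_desc_without`` end-point
    clones must be heterozygous.
    """
    if len(family.markers) != len(potential):
        raise ValueError("family matrix not built on the potential marker set")
    het = family.genotypes == Genotype.HET
    ep = family.endpoint_indices
    n_het_desc = het[:, ep].sum(axis=1)
    if family.founder_idx is not None:
        keep = het[:, family.founder_idx] & (n_het_desc >= min_desc_with_founder)
    else:
        keep = n_het_desc >= min_desc_without
    out = MarkerSet(
        potential.table.loc[np.asarray(keep)].reset_index(drop=True),
        provenance="final",
    )
    return out


@dataclass
class AneuploidyReport:
    chrom_flags: dict[str, bool] = field(default_factory=dict)
    whole_genome: bool = False
    ratios: dict[str, float] = field(default_factory=dict)

    @property
    def flagged(self) -> list[str]:
        return [c for c, v in self.chrom_flags.items() if v]


def detect_aneuploidy(
    per_chrom_allele_depth: Mapping[str, tuple[float, float]],
    genome_mean_depth: float,
    low: float = 0.05,
    high: float = 1.5,
    wgd_tol: float = 0.1,
) -> AneuploidyReport:
    """Flag aneuploid chromosomes from per-allele mean coverage.

    ``per_chrom_allele_depth`` maps chromosome to the mean read depth
    supporting each parental allele.  Depths are normalized by the clone
    genome-wide mean; a chromosome is flagged when either allele's relative
    coverage is below ``low`` or above ``high``.  A whole-genome duplication
    is flagged when the allele coverage ratio sits near 0.5 or 2 (within
    ``wgd_tol``) on every chromosome.
    """
    if genome_mean_depth <= 0:
        raise ValueError("genome mean depth must be positive")
    report = AneuploidyReport()
    for chrom, (d1, d2) in per_chrom_allele_depth.items():
        r1 = d1 / genome_mean_depth
        r2 = d2 / genome_mean_depth
        report.chrom_flags[chrom] = bool(
            r1 < low or r2 < low or r1 > high or r2 > high
        )
        ratio = np.inf if d2 == 0 else d1 / d2
        report.ratios[chrom] = float(ratio)
    # a ratio near 2 is the mirror of a ratio near 0.5, so test the folded
    # ratio min(r, 1/r) against 0.5 on every chromosome
    near = [
        abs(min(r, 1.0 / r if r > 0 else np.inf) - 0.5) <= wgd_tol
        for r in report.ratios.values()
    ]
    report.whole_genome = len(near) > 0 and all(near)
    return report
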