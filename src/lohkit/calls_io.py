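"""Call-set input/output, site-level quality filters, masks and liftover.

Coordinate conventions used throughout the package:

* site positions are 1-based (VCF convention);
* intervals are half-open ``[start, end)`` with a 1-based start, so the
  interval covering the first ten bases of a chromosome is ``(1, 11)``;
* BED files are written 0-based half-open and converted on read/write.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Genotype",
    "SiteCall",
    "GenomeMeta",
    "ChainMap",
    "read_call_set",
    "write_call_set",
    "apply_site_filters",
    "effective_genome_length",
    "merge_intervals",
    "telomere_mask",
    "lift_positions",
    "read_bed",
    "write_bed",
]

#: INFO annotations required on every record.
INFO_KEYS = ("QD", "MQ", "FS", "SOR")


class Genotype(IntEnum):
    """Genotype state in parental-allele space."""

    MISSING = -1
    HOM_P1 = 0
    HET = 1
    HOM_P2 = 2


@dataclass
class SiteCall:
    """A single biallelic SNV call for one sample.

    ``alleles`` is ordered ``(parent1_allele, parent2_allele)`` and
    ``allele_depths`` follows the same orientation, regardless of which
    parental reference the originating VCF was called against.
    """

    chrom: str
    pos: int
    alleles: tuple[str, str]
    genotype: Genotype
    gq: float
    site_qual: float
    depth: int
    allele_depths: tuple[int, int]
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


@dataclass
class GenomeMeta:
    """Chromosome lengths, centromeres and mask intervals.

    Masks are stored per chromosome as half-open 1-based ``(start, end)``
    interval lists on the common coordinate system.
    """

    chrom_lengths: dict[str, int]
    centromeres: dict[str, int] = field(default_factory=dict)
    masks: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, ivs in self.masks.items():
            if chrom not in self.chrom_lengths:
                raise ValueError(f"mask on unknown chromosome {chrom!r}")
            L = self.chrom_lengths[chrom]
            for s, e in ivs:
                if not (1 <= s <= e <= L + 1):
                    raise ValueError(
                        f"mask interval ({s}, {e}) outside chromosome {chrom!r} bounds"
                    )

    def is_masked(self, chrom: str, pos: int) -> bool:
        for s, e in self.masks.get(chrom, ()):
            if s <= pos < e:
                return True
        return False

    def add_masks(self, masks: Mapping[str, Sequence[tuple[int, int]]]) -> None:
        for chrom, ivs in masks.items():
            merged = merge_intervals(list(self.masks.get(chrom, [])) + list(ivs))
            self.masks[chrom] = merged


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly overlapping half-open intervals into a disjoint sorted list."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def effective_genome_length(
    genome_length: int, mask: Sequence[tuple[int, int]]
) -> int:
    """Genome length minus total masked length (mask merged before summing)."""
    masked = sum(e - s for s, e in merge_intervals(mask))
    if masked > genome_length:
        raise ValueError("mask exceeds genome length")
    return genome_length - masked


def telomere_mask(
    chrom_lengths: Mapping[str, int], telomere_bp: int = 7500
) -> dict[str, list[tuple[int, int]]]:
    """Masks covering ``telomere_bp`` at both ends of each chromosome."""
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, L in chrom_lengths.items():
        if L <= 2 * telomere_bp:
            out[chrom] = [(1, L + 1)]
        else:
            out[chrom] = [(1, telomere_bp + 1), (L - telomere_bp + 1, L + 1)]
    return out


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

_GT_FROM_REFPOV = {
    # (ref parent, vcf genotype code) -> parental-space genotype
    ("P1", 0): Genotype.HOM_P1,
    ("P1", 2): Genotype.HOM_P2,
    ("P2", 0): Genotype.HOM_P2,
    ("P2", 2): Genotype.HOM_P1,
}


def read_call_set(
    path: str,
    sample: str,
    ref_parent: str = "P1",
) -> tuple[list[SiteCall], Counter]:
    """Read one sample's biallelic SNV calls from a VCF file.

    Non-SNV and multi-allelic records are dropped and counted; records
    missing a required annotation are dropped and counted.  Genotypes and
    allele depths are re-expressed in parental-allele space according to
    which parent the reference genome derives from (``ref_parent``).

    Returns
    -------
    calls, dropped
        The list of :class:`SiteCall` and a ``Counter`` of drop reasons.
    """
    from cyvcf2 import VCF

    if ref_parent not in ("P1", "P2"):
        raise ValueError("ref_parent must be 'P1' or 'P2'")
    vcf = VCF(path)
    if sample not in vcf.samples:
        raise ValueError(f"sample {sample!r} not in VCF ({vcf.samples})")
    si = vcf.samples.index(sample)

    calls: list[SiteCall] = []
    dropped: Counter = Counter()
    for i, rec in enumerate(vcf):
        try:
            if len(rec.ALT) != 1:
                dropped["multiallelic"] += 1
                continue
            ref, alt = rec.REF, rec.ALT[0]
            if len(ref) != 1 or len(alt) != 1:
                dropped["not_snv"] += 1
                continue
            ann = {}
            missing_info = False
            for key in INFO_KEYS:
                val = rec.INFO.get(key)
                if val is None:
                    missing_info = True
                    break
                ann[key] = float(val)
            if missing_info:
                dropped["missing_annotation"] += 1
                continue

            gt_code = rec.gt_types[si]  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            if gt_code == 2:
                genotype = Genotype.MISSING
                gq = float("nan")
            elif gt_code == 1:
                genotype = Genotype.HET
                gq = float(rec.gt_quals[si])
            else:
                code = 0 if gt_code == 0 else 2
                genotype = _GT_FROM_REFPOV[(ref_parent, code)]
                gq = float(rec.gt_quals[si])

            ad = rec.format("AD")
            if ad is None:
                dropped["missing_annotation"] += 1
                continue
            ad_ref, ad_alt = int(ad[si][0]), int(ad[si][1])
            dp = rec.format("DP")
            depth = int(dp[si][0]) if dp is not None else ad_ref + ad_alt
            if depth < 0:
                depth = ad_ref + ad_alt

            if ref_parent == "P1":
                alleles = (ref, alt)
                allele_depths = (ad_ref, ad_alt)
            else:
                alleles = (alt, ref)
                allele_depths = (ad_alt, ad_ref)

            calls.append(
                SiteCall(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    alleles=alleles,
                    genotype=genotype,
                    gq=gq,
                    site_qual=float(rec.QUAL) if rec.QUAL is not None else 0.0,
                    depth=depth,
                    allele_depths=allele_depths,
                    annotations=ann,
                )
            )
        except (ValueError, TypeError, IndexError) as exc:
            raise ValueError(f"malformed VCF record #{i + 1} at {path}") from exc
    if dropped:
        logger.info("read_call_set(%s): dropped %s", sample, dict(dropped))
    return calls, dropped


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=QD,Number=1,Type=Float,Description="QualByDepth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMSMappingQuality">
##INFO=<ID=FS,Number=1,Type=Float,Description="FisherStrand">
##INFO=<ID=SOR,Number=1,Type=Float,Description="SymmetricOddsRatio">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="GenotypeQuality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AlleleDepths">
"""

_GT_TO_VCF = {
    ("P1", Genotype.HOM_P1): "0/0",
    ("P1", Genotype.HET): "0/1",
    ("P1", Genotype.HOM_P2): "1/1",
    ("P2", Genotype.HOM_P2): "0/0",
    ("P2", Genotype.HET): "0/1",
    ("P2", Genotype.HOM_P1): "1/1",
}


def write_call_set(
    path: str,
    calls: Iterable[SiteCall],
    sample: str,
    ref_parent: str = "P1",
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write calls as an uncompressed single-sample VCF.

    Inverse of :func:`read_call_set` with the same ``ref_parent``.
    """
    if ref_parent not in ("P1", "P2"):
        raise ValueError("ref_parent must be 'P1' or 'P2'")
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        if contigs:
            for chrom, L in contigs.items():
                fh.write(f"##contig=<ID={chrom},length={L}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for c in calls:
            if ref_parent == "P1":
                ref, alt = c.alleles
                ad = c.allele_depths
            else:
                alt, ref = c.alleles
                ad = (c.allele_depths[1], c.allele_depths[0])
            if c.genotype == Genotype.MISSING:
                gt, gq = "./.", "."
            else:
                gt = _GT_TO_VCF[(ref_parent, c.genotype)]
                gq = str(int(round(c.gq)))
            info = ";".join(f"{k}={c.annotations.get(k, 0.0):g}" for k in INFO_KEYS)
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{ref}\t{alt}\t{c.site_qual:g}\tPASS\t"
                f"{info}\tGT:GQ:DP:AD\t{gt}:{gq}:{c.depth}:{ad[0]},{ad[1]}\n"
            )


# ---------------------------------------------------------------------------
# Site filters
# ---------------------------------------------------------------------------


def apply_site_filters(
    calls: Sequence[SiteCall],
    sample_median_depth: float,
    meta: GenomeMeta,
    qual_min: float = 1000.0,
    depth_min: int = 6,
    depth_cap_mult: float = 5.0,
    qd_min: float = 2.0,
    mq_min: float = 20.0,
    fs_max: float = 60.0,
    sor_max: float = 10.0,
    gq_min: float | None = None,
) -> tuple[list[SiteCall], Counter]:
    """Apply the hard site-level quality filters and the genomic masks.

    All filters are conjunctive predicates; a call failing several rules is
    tallied once under the first failing rule in the order below (the
    surviving set is order-independent).  ``gq_min`` is optional because the
    dual-reference route defers the GQ threshold to reconciliation.
    """
    if sample_median_depth <= 0:
        raise ValueError("sample_median_depth must be positive")
    kept: list[SiteCall] = []
    removed: Counter = Counter()
    depth_cap = depth_cap_mult * sample_median_depth
    for c in calls:
        ann = c.annotations
        if ann.get("QD", np.inf) < qd_min:
            removed["QD"] += 1
        elif ann.get("MQ", np.inf) < mq_min:
            removed["MQ"] += 1
        elif ann.get("FS", -np.inf) > fs_max:
            removed["FS"] += 1
        elif ann.get("SOR", -np.inf) > sor_max:
            removed["SOR"] += 1
        elif c.depth < depth_min:
            removed["depth_min"] += 1
        elif c.depth > depth_cap:
            removed["depth_cap"] += 1
        elif c.site_qual < qual_min:
            removed["QUAL"] += 1
        elif meta.is_masked(c.chrom, c.pos):
            removed["mask"] += 1
        elif gq_min is not None and not (_gq_or_zero(c) >= gq_min):
            removed["GQ"] += 1
        else:
            kept.append(c)
    return kept, removed


def _gq_or_zero(call: SiteCall) -> float:
    # missing GQ is treated as 0: fails every GQ threshold
    gq = call.gq
    return 0.0 if gq is None or np.isnan(gq) else gq


# ---------------------------------------------------------------------------
# Liftover
# ---------------------------------------------------------------------------


class ChainMap:
    """Ordered alignment blocks mapping source to target coordinates.

    Blocks are ``(src_start, src_end, tgt_start)`` half-open 1-based per
    chromosome, non-overlapping and sorted in both coordinate systems.
    """

    def __init__(self, blocks: Mapping[str, Sequence[tuple[int, int, int]]]):
        self.blocks: dict[str, np.ndarray] = {}
        for chrom, blk in blocks.items():
            arr = np.asarray(sorted(blk), dtype=np.int64).reshape(-1, 3)
            if np.any(arr[:, 1] < arr[:, 0]):
                raise ValueError(f"negative-length block on {chrom!r}")
            if np.any(arr[1:, 0] < arr[:-1, 1]):
                raise ValueError(f"overlapping source blocks on {chrom!r}")
            tgt_end = arr[:, 2] + (arr[:, 1] - arr[:, 0])
            if np.any(arr[1:, 2] < tgt_end[:-1]):
                raise ValueError(f"overlapping target blocks on {chrom!r}")
            self.blocks[chrom] = arr

    @classmethod
    def identity(cls, chrom_lengths: Mapping[str, int]) -> "ChainMap":
        return cls({c: [(1, L + 1, 1)] for c, L in chrom_lengths.items()})

    @classmethod
    def from_file(cls, path: str) -> "ChainMap":
        """Parse a UCSC chain file (plus-strand alignments only).

        The chain's target (``tName``) is taken as the source coordinate
        system and its query (``qName``) as the destination, matching the
        orientation of liftover chains.
        """
        blocks: dict[str, list[tuple[int, int, int]]] = {}
        with open(path) as fh:
            chrom = None
            t_pos = q_pos = 0
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if parts[0] == "chain":
                    if len(parts) < 12:
                        raise ValueError(f"malformed chain header at line {lineno}")
                    chrom = parts[2]
                    if parts[4] != "+" or parts[9] != "+":
                        raise ValueError(
                            f"only plus-strand chains supported (line {lineno})"
                        )
                    t_pos = int(parts[5])  # 0-based
                    q_pos = int(parts[10])
                    blocks.setdefault(chrom, [])
                else:
                    if chrom is None:
                        raise ValueError(f"alignment line before header (line {lineno})")
                    size = int(parts[0])
                    blocks[chrom].append((t_pos + 1, t_pos + size + 1, q_pos + 1))
                    if len(parts) == 3:
                        t_pos += size + int(parts[1])
                        q_pos += size + int(parts[2])
                    else:
                        chrom = None
        return cls(blocks)

    def write(self, path: str, chrom_sizes: Mapping[str, int] | None = None) -> None:
        with open(path, "w") as fh:
            for chrom, arr in self.blocks.items():
                if len(arr) == 0:
                    continue
                t0 = int(arr[0, 0] - 1)
                t_end = int(arr[-1, 1] - 1)
                q0 = int(arr[0, 2] - 1)
                q_end = int(arr[-1, 2] - 1 + arr[-1, 1] - arr[-1, 0])
                t_size = chrom_sizes.get(chrom, t_end) if chrom_sizes else t_end
                fh.write(
                    f"chain 1000 {chrom} {t_size} + {t0} {t_end} "
                    f"{chrom} {q_end} + {q0} {q_end} 1\n"
                )
                for i in range(len(arr)):
                    size = int(arr[i, 1] - arr[i, 0])
                    if i < len(arr) - 1:
                        dt = int(arr[i + 1, 0] - arr[i, 1])
                        dq = int(arr[i + 1, 2] - (arr[i, 2] + size))
                        fh.write(f"{size} {dt} {dq}\n")
                    else:
                        fh.write(f"{size}\n")
                fh.write("\n")


def lift_positions(
    chain: ChainMap, chrom: str, positions: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Map 1-based positions through a chain.

    Returns ``(mapped, unmapped)`` where ``mapped`` holds target positions
    (arbitrary where unmapped) and ``unmapped`` is a boolean mask; positions
    in alignment gaps or beyond chromosome bounds are flagged, never raised.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if chrom not in chain.blocks or len(chain.blocks[chrom]) == 0:
        return pos.copy(), np.ones(len(pos), dtype=bool)
    arr = chain.blocks[chrom]
    idx = np.searchsorted(arr[:, 0], pos, side="right") - 1
    idx_c = np.clip(idx, 0, len(arr) - 1)
    inside = (idx >= 0) & (pos >= arr[idx_c, 0]) & (pos < arr[idx_c, 1])
    mapped = pos.copy()
    mapped[inside] = pos[inside] - arr[idx_c[inside], 0] + arr[idx_c[inside], 2]
    return mapped, ~inside


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path: str) -> dict[str, list[tuple[int, int]]]:
    """Read a BED file into 1-based half-open intervals per chromosome."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            out.setdefault(chrom, []).append((start + 1, end + 1))
    return {c: merge_intervals(iv) for c, iv in out.items()}


def write_bed(path: str, intervals: Mapping[str, Sequence[tuple[int, int]]]) -> None:
    """Write 1-based half-open intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        for chrom in intervals:
            for s, e in sorted(intervals[chrom]):
                fh.write(f"{chrom}\t{s - 1}\t{e - 1}\n")
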