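"""LOH tract detection, event merging, classification and bias statistics.

An LOH *tract* is a maximal run of adjacent markers homozygous for the same
parental allele ("converted markers"); missing calls are transparent and do
not break a run.  Tracts whose facing boundaries lie closer than a gap
threshold are merged into *events*, which are terminal when a boundary is a
chromosome end and interstitial otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calls_io import Genotype

logger = logging.getLogger(__name__)

__all__ = [
    "LohTract",
    "LohEvent",
    "find_tracts",
    "merge_into_events",
    "classify_events",
    "breakpoint_position",
    "homolog_bias",
    "tile_windows",
    "hchb_scan",
    "benjamini_hochberg",
    "events_to_frame",
]

P1, P2 = "P1", "P2"
_HOMOLOG = {int(Genotype.HOM_P1): P1, int(Genotype.HOM_P2): P2}


@dataclass
class LohTract:
    clone: str
    chrom: str
    first_marker: int  # position of first converted marker
    last_marker: int
    start: int  # boundary interval, 1-based inclusive
    end: int
    homolog: str
    n_markers: int
    left_terminal: bool = False
    right_terminal: bool = False

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ValueError("tract must contain at least one converted marker")
        if not (self.start <= self.first_marker <= self.last_marker <= self.end):
            raise ValueError("tract boundaries must bracket the converted markers")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class LohEvent:
    clone: str
    chrom: str
    start: int
    end: int
    homolog: str
    tracts: list[LohTract] = field(default_factory=list)
    type: str | None = None  # interstitial | terminal
    breakpoint: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_markers(self) -> int:
        return sum(t.n_markers for t in self.tracts)

    @property
    def left_terminal(self) -> bool:
        return any(t.left_terminal for t in self.tracts) or self.start == 1

    @property
    def right_terminal(self) -> bool:
        return any(t.right_terminal for t in self.tracts)


def find_tracts(
    positions: Sequence[int],
    genotypes: Sequence[int],
    chrom_length: int,
    clone: str = "",
    chrom: str = "",
) -> list[LohTract]:
    """Find maximal same-homolog homozygous runs along one chromosome.

    ``positions`` must be strictly increasing marker positions with
    genotype states in {HOM_P1, HET, HOM_P2, MISSING}.  Adjacency is
    evaluated over non-missing markers only.  Internal boundaries sit at
    the (floored) midpoint between the outermost converted marker and the
    adjacent unconverted marker; a tract containing the first (last)
    non-missing marker extends to the chromosome start (end).
    """
    pos = np.asarray(positions, dtype=np.int64)
    gt = np.asarray(genotypes, dtype=np.int8)
    if len(pos) != len(gt):
        raise ValueError("positions and genotypes must align")
    if np.any(np.diff(pos) <= 0):
        raise ValueError("marker positions must be strictly increasing")

    keep = gt != Genotype.MISSING
    pos = pos[keep]
    gt = gt[keep]
    n = len(pos)
    if n == 0:
        return []

    tracts: list[LohTract] = []
    i = 0
    while i < n:
        if gt[i] not in (Genotype.HOM_P1, Genotype.HOM_P2):
            i += 1
            continue
        j = i
        while j + 1 < n and gt[j + 1] == gt[i]:
            j += 1
        first, last = int(pos[i]), int(pos[j])
        left_terminal = i == 0
        right_terminal = j == n - 1
        start = 1 if left_terminal else (int(pos[i - 1]) + first) // 2
        end = chrom_length if right_terminal else (last + int(pos[j + 1])) // 2
        tracts.append(
            LohTract(
                clone=clone,
                chrom=chrom,
                first_marker=first,
                last_marker=last,
                start=start,
                end=end,
                homolog=_HOMOLOG[int(gt[i])],
                n_markers=j - i + 1,
                left_terminal=left_terminal,
                right_terminal=right_terminal,
            )
        )
        i = j + 1
    return tracts


def merge_into_events(
    tracts: Sequence[LohTract], gap_bp: int = 10_000
) -> list[LohEvent]:
    """Merge tracts whose facing boundaries are separated by < ``gap_bp``.

    Merging is transitive and crosses homolog labels; the merged event is
    ascribed the homolog with the greatest total conversion length across
    member tracts (tie -> P1, logged).  Tracts must belong to one clone and
    one chromosome.
    """
    if not tracts:
        return []
    srt = sorted(tracts, key=lambda t: t.start)
    groups: list[list[LohTract]] = [[srt[0]]]
    for t in srt[1:]:
        prev = groups[-1][-1]
        if t.start - prev.end < gap_bp:
            groups[-1].append(t)
        else:
            groups.append([t])

    events: list[LohEvent] = []
    for grp in groups:
        length_by_homolog = {P1: 0, P2: 0}
        for t in grp:
            length_by_homolog[t.homolog] += t.length
        if length_by_homolog[P1] == length_by_homolog[P2]:
            homolog = P1
            if len({t.homolog for t in grp}) > 1:
                logger.warning(
                    "homolog tie in merged event at %s:%d; assigning P1",
                    grp[0].chrom,
                    grp[0].start,
                )
        else:
            homolog = max(length_by_homolog, key=length_by_homolog.get)
        events.append(
            LohEvent(
                clone=grp[0].clone,
                chrom=grp[0].chrom,
                start=grp[0].start,
                end=max(t.end for t in grp),
                homolog=homolog,
                tracts=list(grp),
            )
        )
    return events


def classify_events(
    events: Sequence[LohEvent], chrom_lengths: Mapping[str, int]
) -> list[LohEvent]:
    """Label events terminal/interstitial in place and return them.

    An event is terminal iff one of its boundaries is a chromosome end; an
    event spanning the centromere with both ends internal stays
    interstitial.  Whole-chromosome events are terminal at both ends and
    flagged with a warning.
    """
    for ev in events:
        L = chrom_lengths[ev.chrom] if ev.chrom in chrom_lengths else None
        left = ev.start == 1
        right = L is not None and ev.end == L
        ev.type = "terminal" if (left or right) else "interstitial"
        if left and right:
            logger.warning(
                "whole-chromosome event in clone %s on %s", ev.clone, ev.chrom
            )
    return list(events)


def breakpoint_position(
    event: LohEvent,
    centromere: int | None = None,
    long_tloh_bp: int = 20_000,
    offset_bp: int = 10_000,
) -> int:
    """Estimated DNA-break position for an event.

    The midpoint of the boundaries for interstitial events and short
    terminal events; for terminal events longer than ``long_tloh_bp`` the
    position ``offset_bp`` inside the event from its centromere-proximal
    boundary.
    """
    if event.type is None:
        raise ValueError("classify events before computing breakpoints")
    if event.type == "interstitial" or event.length <= long_tloh_bp:
        bp = (event.start + event.end) // 2
    else:
        if centromere is None:
            raise ValueError(
                f"centromere position required for long terminal event on "
                f"{event.chrom}"
            )
        if event.start == 1 and not event.right_terminal:
            bp = event.end - offset_bp  # left-arm tLOH: proximal boundary is end
        else:
            bp = event.start + offset_bp
    event.breakpoint = int(bp)
    return int(bp)


@dataclass
class BiasResult:
    n_p1: int
    n_p2: int

    @property
    def total(self) -> int:
        return self.n_p1 + self.n_p2

    @property
    def fraction_p1(self) -> float | None:
        return None if self.total == 0 else self.n_p1 / self.total

    @property
    def p_value(self) -> float | None:
        if self.total == 0:
            return None
        return float(stats.binomtest(self.n_p1, self.total, 0.5).pvalue)


def homolog_bias(
    events: Sequence[LohEvent], by_type: bool = True
) -> dict[str, BiasResult]:
    """Homolog-bias counts and exact binomial tests, overall and per type."""
    out: dict[str, BiasResult] = {}

    def tally(evs):
        n1 = sum(1 for e in evs if e.homolog == P1)
        return BiasResult(n_p1=n1, n_p2=len(evs) - n1)

    out["all"] = tally(events)
    if by_type:
        for t in ("interstitial", "terminal"):
            out[t] = tally([e for e in events if e.type == t])
    return out


def tile_windows(
    chrom_length: int, window_bp: int = 50_000, end_rule_bp: int = 25_000
) -> list[tuple[int, int]]:
    """Partition a chromosome into ~``window_bp`` windows.

    ``K = floor(L / w)`` core windows are centred so that ``r = (L - K w)/2``
    remains at each end.  If ``r > end_rule_bp`` the remainders become
    separate end windows; otherwise they are merged into the terminal core
    windows.  Returned intervals are half-open 1-based and partition
    ``[1, L + 1)`` exactly.
    """
    L, w = int(chrom_length), int(window_bp)
    if L < w:
        return [(1, L + 1)]
    K = L // w
    r = (L - K * w) / 2.0
    if r == 0:
        edges = [1 + i * w for i in range(K + 1)]
    elif r > end_rule_bp:
        r_lo = int(np.floor(r))
        edges = [1, 1 + r_lo] + [1 + r_lo + i * w for i in range(1, K + 1)] + [L + 1]
    else:
        if K == 1:
            return [(1, L + 1)]
        r_lo = int(np.floor(r))
        edges = [1] + [1 + r_lo + i * w for i in range(1, K)] + [L + 1]
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def _binom_pval_half(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorized exact two-sided binomial p-value at p = 0.5.

    By symmetry the two-sided p-value is the probability of a count at
    least as far from n/2 as observed: ``P(X <= m) + P(X >= n - m)`` with
    ``m = min(k, n - k)``.  Empty windows (n = 0) get p = 1.
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    p = np.ones(k.shape, dtype=float)
    pos = n > 0
    m = np.minimum(k[pos], n[pos] - k[pos])
    lower = stats.binom.cdf(m, n[pos], 0.5)
    upper = stats.binom.sf(n[pos] - m - 1, n[pos], 0.5)
    even_center = (n[pos] % 2 == 0) & (m == n[pos] // 2)
    out = np.minimum(lower + upper, 1.0)
    out[even_center] = 1.0  # both tails double-count the central atom
    p[pos] = out
    return p


def hchb_scan(
    events: Sequence[LohEvent],
    windows_by_chrom: Mapping[str, Sequence[tuple[int, int]]],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Scan windows for high-conversion high-bias signatures.

    Event breakpoints (which must be assigned already) are counted per
    window and homolog; each window gets an exact two-sided binomial
    p-value at P = 0.5, Benjamini-Hochberg adjusted across *all* genome
    windows; windows with ``q <= fdr`` are flagged HCHB.  Empty windows get
    p = 1 by convention.
    """
    rows = []
    for chrom, windows in windows_by_chrom.items():
        chrom_events = [e for e in events if e.chrom == chrom]
        bps = np.array([e.breakpoint for e in chrom_events], dtype=float)
        if np.any(np.isnan(bps)):
            raise ValueError("all events need assigned breakpoints")
        hom = np.array([e.homolog == P1 for e in chrom_events])
        for s, e in windows:
            inside = (bps >= s) & (bps < e) if len(bps) else np.zeros(0, bool)
            n1 = int(np.sum(hom & inside)) if len(bps) else 0
            n2 = int(np.sum(~hom & inside)) if len(bps) else 0
            rows.append((chrom, s, e, n1, n2))
    tab = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_p1", "n_p2"])
    n = (tab["n_p1"] + tab["n_p2"]).to_numpy()
    tab["p"] = _binom_pval_half(tab["n_p1"].to_numpy(), n)
    tab["q"] = benjamini_hochberg(tab["p"].to_numpy())
    tab["hchb"] = tab["q"] <= fdr
    n_empty = int((n == 0).sum())
    if n_empty:
        logger.info("hchb_scan: %d empty windows assigned p = 1", n_empty)
    return tab


def events_to_frame(events: Sequence[LohEvent]) -> pd.DataFrame:
    """Flatten events into a deterministic, sorted table."""
    rows = [
        {
            "clone": e.clone,
            "chrom": e.chrom,
            "start": e.start,
            "end": e.end,
            "length": e.length,
            "type": e.type,
            "homolog": e.homolog,
            "n_markers": e.n_markers,
            "breakpoint": e.breakpoint,
        }
        for e in events
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "clone",
            "chrom",
            "start",
            "end",
            "length",
            "type",
            "homolog",
            "n_markers",
            "breakpoint",
        ],
    )
    return df.sort_values(["clone", "chrom", "start"], kind="mergesort").reset_index(
        drop=True
    )
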