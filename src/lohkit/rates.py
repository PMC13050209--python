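"""Event-rate and conversion-rate estimation with undercount corrections.

Three undercounts are corrected: events falling between markers (detection
probability model over log-length bins), overlapping interstitial events
(closed-form collision probability, diagnostics only) and multiple terminal
events on one arm (the P0 estimator, which only uses the zero class).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "detection_probability",
    "correct_intermarker",
    "intermarker_width_sensitivity",
    "IntermarkerCorrection",
    "iloh_rates",
    "tloh_rates_p0",
    "overlap_probability_iloh",
    "overlap_probability_tloh",
    "conversion_rates",
    "local_rates",
    "effective_length_fraction_masked",
    "erroneous_single_reference",
]


def detection_probability(
    length: float | np.ndarray, n_markers: int, genome_length: float
) -> float | np.ndarray:
    """Probability that an event of the given length covers >= 1 marker.

    ``P_detect(l) = 1 - (1 - l/L)^n`` for markers uniform on a genome of
    length ``L``; computed via ``log1p`` for numerical stability.
    """
    l = np.asarray(length, dtype=float)
    if np.any(l < 0) or np.any(l > genome_length):
        raise ValueError("length must lie in [0, genome_length]")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -np.expm1(n_markers * np.log1p(-l / genome_length))
    out = np.where(l >= genome_length, 1.0, out)
    return float(out) if np.isscalar(length) else out


@dataclass
class IntermarkerCorrection:
    """Binned inter-marker undercount correction."""

    table: pd.DataFrame  # columns: log10_lo, log10_hi, n_detected, mean_len, p_detect, n_corrected
    total_detected: int
    total_corrected: float

    @property
    def factor(self) -> float:
        """Multiplier taking detected totals to corrected totals."""
        if self.total_detected == 0:
            return 1.0
        return self.total_corrected / self.total_detected


def correct_intermarker(
    event_lengths: Sequence[float],
    n_markers: int,
    genome_length: float,
    bin_width_log10: float = 0.25,
) -> IntermarkerCorrection:
    """Correct detected event counts for events that fell between markers.

    Events are binned by log10 length; each bin's count is divided by the
    detection probability evaluated at the bin's mean detected length.
    Interior empty bins (flanked on both sides by nonempty bins) receive a
    pseudocount of 1 before correction, at the bin-centre length.
    """
    lengths = np.asarray(event_lengths, dtype=float)
    if len(lengths) == 0:
        return IntermarkerCorrection(
            table=pd.DataFrame(
                columns=[
                    "log10_lo",
                    "log10_hi",
                    "n_detected",
                    "mean_len",
                    "p_detect",
                    "n_corrected",
                ]
            ),
            total_detected=0,
            total_corrected=0.0,
        )
    if np.any(lengths < 1):
        raise ValueError("event lengths must be >= 1 bp")

    logs = np.log10(lengths)
    lo_edge = np.floor(logs.min() / bin_width_log10) * bin_width_log10
    hi_edge = np.ceil(logs.max() / bin_width_log10 + 1e-9) * bin_width_log10
    n_bins = max(1, int(round((hi_edge - lo_edge) / bin_width_log10)))
    edges = lo_edge + bin_width_log10 * np.arange(n_bins + 1)
    idx = np.clip(np.digitize(logs, edges) - 1, 0, n_bins - 1)

    counts = np.bincount(idx, minlength=n_bins).astype(float)
    sums = np.bincount(idx, weights=lengths, minlength=n_bins)
    mean_len = np.full(n_bins, np.nan)
    nonzero = counts > 0
    mean_len[nonzero] = sums[nonzero] / counts[nonzero]

    # interior empty bins get pseudocount 1 at the (geometric) bin centre
    occupied = np.flatnonzero(nonzero)
    for b in range(occupied[0] + 1, occupied[-1]):
        if counts[b] == 0:
            counts[b] = 1.0
            mean_len[b] = 10 ** ((edges[b] + edges[b + 1]) / 2.0)

    used = counts > 0
    p_det = np.full(n_bins, np.nan)
    p_det[used] = detection_probability(
        np.minimum(mean_len[used], genome_length), n_markers, genome_length
    )
    corrected = np.full(n_bins, 0.0)
    corrected[used] = counts[used] / p_det[used]

    tab = pd.DataFrame(
        {
            "log10_lo": edges[:-1],
            "log10_hi": edges[1:],
            "n_detected": np.bincount(idx, minlength=n_bins),
            "mean_len": mean_len,
            "p_detect": p_det,
            "n_corrected": corrected,
        }
    )
    return IntermarkerCorrection(
        table=tab,
        total_detected=int(len(lengths)),
        total_corrected=float(corrected.sum()),
    )


def intermarker_width_sensitivity(
    event_lengths: Sequence[float],
    n_markers: int,
    genome_length: float,
    widths: Sequence[float] = (0.125, 0.25, 0.5),
) -> pd.DataFrame:
    """Diagnostic: corrected totals as a function of the log10 bin width."""
    rows = [
        (
            w,
            correct_intermarker(
                event_lengths, n_markers, genome_length, bin_width_log10=w
            ).total_corrected,
        )
        for w in widths
    ]
    return pd.DataFrame(rows, columns=["bin_width_log10", "total_corrected"])


@dataclass
class RateEstimates:
    """Per-arm and genome-wide rate estimates for one hybrid."""

    per_arm: dict[str, float] = field(default_factory=dict)
    genome_wide: float = 0.0
    genome_wide_corrected: float | None = None


def iloh_rates(
    counts: Mapping[str, Sequence[int]],
    generations: float,
    intermarker_factor: float = 1.0,
    tloh_masked_fraction: float = 0.0,
) -> RateEstimates:
    """Interstitial event rates from per-arm per-clone counts.

    ``counts[arm]`` holds one event count per clone.  The per-arm rate is
    the mean count over clones divided by ``generations``; the genome-wide
    rate sums the arms, is multiplied by the inter-marker correction factor
    and divided by the mean fraction of the genome not masked by terminal
    events.
    """
    if generations <= 0:
        raise ValueError("generations must be positive")
    if not 0 <= tloh_masked_fraction < 1:
        raise ValueError("tloh_masked_fraction must be in [0, 1)")
    est = RateEstimates()
    for arm, c in counts.items():
        c = np.asarray(c, dtype=float)
        est.per_arm[arm] = float(c.mean() / generations)
    est.genome_wide = float(sum(est.per_arm.values()))
    est.genome_wide_corrected = (
        est.genome_wide * intermarker_factor / (1.0 - tloh_masked_fraction)
    )
    return est


def tloh_rates_p0(
    indicators: Mapping[str, Sequence[int]], generations: float
) -> RateEstimates:
    """Terminal event rates via the P0 method.

    ``indicators[arm]`` holds 0/1 per clone (any terminal event on that arm
    or not).  With ``p0 = (sum(1 - C) + 1) / (n + 1)`` (pseudocount 1), the
    arm rate is ``-ln(p0) / T``; the genome-wide rate sums the arms.
    """
    if generations <= 0:
        raise ValueError("generations must be positive")
    est = RateEstimates()
    for arm, c in indicators.items():
        c = np.asarray(c, dtype=float)
        if np.any((c != 0) & (c != 1)):
            raise ValueError("tLOH indicators must be 0/1")
        n = len(c)
        p0 = (np.sum(1.0 - c) + 1.0) / (n + 1.0)
        est.per_arm[arm] = float(-np.log(p0) / generations)
    est.genome_wide = float(sum(est.per_arm.values()))
    return est


def overlap_probability_iloh(k: float, length: float, genome_length: float) -> float:
    """Probability that at least one pair of ``k`` uniform events overlap.

    ``P = 1 - (1 - 2 l / L)^(k (k - 1) / 2)``; ``k`` may be non-integer
    (a mean count used as exponent).
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if k <= 1:
        return 0.0
    pairs = k * (k - 1.0) / 2.0
    return float(-np.expm1(pairs * np.log1p(-2.0 * length / genome_length)))


def overlap_probability_tloh(
    k: float, m: float, length: float, tloh_length: float, genome_length: float
) -> float:
    """Probability that any of ``k`` interstitial events hits any of ``m``
    terminal events: ``P = 1 - (1 - (s + l/2)/L)^(k m)``."""
    if k < 0 or m < 0:
        raise ValueError("k and m must be non-negative")
    if k == 0 or m == 0:
        return 0.0
    per = (tloh_length + length / 2.0) / genome_length
    return float(-np.expm1(k * m * np.log1p(-per)))


@dataclass
class ConversionRates:
    total: float
    interstitial: float
    terminal: float


def conversion_rates(
    iloh_lengths: Sequence[float],
    tloh_lengths: Sequence[float],
    n_clones: int,
    effective_length: float,
    generations: float,
    mean_tloh_masked_bp: float = 0.0,
) -> ConversionRates:
    """Per-bp per-generation conversion rates.

    Total and terminal rates divide summed event lengths by
    ``n_clones * effective_length * generations``; the interstitial rate
    uses ``effective_length - mean_tloh_masked_bp`` as its denominator.
    """
    if n_clones <= 0 or generations <= 0:
        raise ValueError("n_clones and generations must be positive")
    if effective_length <= mean_tloh_masked_bp:
        raise ValueError("effective length must exceed the tLOH-masked mean")
    s_i = float(np.sum(iloh_lengths)) if len(iloh_lengths) else 0.0
    s_t = float(np.sum(tloh_lengths)) if len(tloh_lengths) else 0.0
    denom = n_clones * generations
    return ConversionRates(
        total=(s_i + s_t) / (denom * effective_length),
        interstitial=s_i / (denom * (effective_length - mean_tloh_masked_bp)),
        terminal=s_t / (denom * effective_length),
    )


def local_rates(
    breakpoints: Sequence[int],
    windows: Sequence[tuple[int, int]],
    n_clones: int,
    generations: float,
) -> pd.DataFrame:
    """Per-window event rates from breakpoint counts on one chromosome.

    Rate = count / (window length * n_clones * generations).
    """
    if n_clones <= 0 or generations <= 0:
        raise ValueError("n_clones and generations must be positive")
    bps = np.asarray(breakpoints, dtype=np.int64)
    rows = []
    for s, e in windows:
        count = int(np.sum((bps >= s) & (bps < e)))
        rows.append((s, e, count, count / ((e - s) * n_clones * generations)))
    return pd.DataFrame(rows, columns=["start", "end", "count", "rate"])


def effective_length_fraction_masked(genome_length: float, masked_bp: float) -> float:
    """Percentage of the genome excluded by the masks."""
    if not 0 <= masked_bp <= genome_length:
        raise ValueError("masked length must lie within the genome")
    return 100.0 * masked_bp / genome_length


def erroneous_single_reference(
    n_toward_ref: int, n_toward_other: int
) -> tuple[int, int, float]:
    """Rough excess-over-parity estimate of erroneous single-reference events.

    Assuming no true conversion bias and that all erroneous events convert
    toward the reference homolog, the non-reference count equals the true
    per-homolog count, so the excess ``n_toward_ref - n_toward_other`` is
    spurious.  Returns ``(excess, total, percent_of_total)``.
    """
    if min(n_toward_ref, n_toward_other) < 0:
        raise ValueError("counts must be non-negative")
    excess = n_toward_ref - n_toward_other
    total = n_toward_ref + n_toward_other
    pct = 100.0 * excess / total if total else 0.0
    return excess, total, pct
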