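"""Sample-specific differential methylation calls.

With one enriched library per condition and no biological replicates, the
contrast is presence/absence: a peak found only in the treated sample is
a treatment-induced hypermethylation site, a peak found only in the
control is a hypomethylation site (the treatment lost it), and peaks
overlapping between samples are shared.  Each call also carries a
normalized difference — the contrast of library-size-normalized read
counts in the peak span, bounded in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .annotate import AnnotatedPeak
from .io import ReadAlignment
from .peaks import Peak, five_prime_positions

HYPER = "hyper"
HYPO = "hypo"
SHARED = "shared"
LABELS = (HYPER, HYPO, SHARED)


@dataclass
class DifferentialCall:
    peak: AnnotatedPeak | Peak
    sample: str                      # "treated" or "control"
    label: str                       # hyper / hypo / shared
    normalized_difference: float = np.nan
    normalized_difference_degenerate: bool = False
    partner_peak: int | None = None  # index into the other sample's peak list

    @property
    def span(self) -> tuple[str, int, int]:
        p = self.peak.peak if isinstance(self.peak, AnnotatedPeak) else self.peak
        return p.chrom, p.start, p.end


def _span(p) -> tuple[str, int, int]:
    q = p.peak if isinstance(p, AnnotatedPeak) else p
    return q.chrom, q.start, q.end


def _overlaps(
    peaks_a: Sequence, peaks_b: Sequence, min_overlap_bp: int
) -> dict[int, int]:
    """Map index in ``peaks_a`` -> index of its largest-overlap partner in
    ``peaks_b`` among partners overlapping by >= min_overlap_bp."""
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, p in enumerate(peaks_b):
        chrom, s, e = _span(p)
        by_chrom.setdefault(chrom, []).append((s, e, j))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    partners: dict[int, int] = {}
    for i, p in enumerate(peaks_a):
        chrom, s, e = _span(p)
        best_ovl, best_j = 0, None
        for bs, be, j in by_chrom.get(chrom, []):
            if bs >= e:
                break
            ovl = min(e, be) - max(s, bs)
            if ovl >= min_overlap_bp and (ovl > best_ovl):
                best_ovl, best_j = ovl, j
        if best_j is not None:
            partners[i] = best_j
    return partners


def classify_differential(
    peaks_treated: Sequence,
    peaks_control: Sequence,
    min_overlap_bp: int = 1,
) -> list[DifferentialCall]:
    """Label every peak from both samples as hyper, hypo or shared.

    A treated peak overlapping any control peak by >= ``min_overlap_bp``
    is shared (and symmetrically); treated-only peaks are hyper, control-
    only peaks hypo.  Shared peaks record their largest-overlap partner.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    t_partner = _overlaps(peaks_treated, peaks_control, min_overlap_bp)
    c_partner = _overlaps(peaks_control, peaks_treated, min_overlap_bp)
    calls: list[DifferentialCall] = []
    for i, p in enumerate(peaks_treated):
        if i in t_partner:
            calls.append(DifferentialCall(p, "treated", SHARED,
                                          partner_peak=t_partner[i]))
        else:
            calls.append(DifferentialCall(p, "treated", HYPER))
    for j, p in enumerate(peaks_control):
        if j in c_partner:
            calls.append(DifferentialCall(p, "control", SHARED,
                                          partner_peak=c_partner[j]))
        else:
            calls.append(DifferentialCall(p, "control", HYPO))
    return calls


def normalized_difference_counts(
    count_treated: int, lib_treated: int, count_control: int, lib_control: int
) -> tuple[float, bool]:
    """(a - b)/(a + b) on counts-per-million; (0, degenerate) when a + b = 0."""
    if lib_treated <= 0 or lib_control <= 0:
        raise ValueError("library sizes must be > 0")
    a = 1e6 * count_treated / lib_treated
    b = 1e6 * count_control / lib_control
    if a + b == 0:
        return 0.0, True
    return (a - b) / (a + b), False


def normalized_difference(
    peak,
    reads_treated: Sequence[ReadAlignment],
    reads_control: Sequence[ReadAlignment],
) -> float:
    """Normalized difference of a peak's span between the two read sets.

    Reads are counted in the span by their 5' coordinate, consistent with
    window and peak counting; positive values mean treated-enriched.
    """
    chrom, start, end = _span(peak)
    value, _ = normalized_difference_counts(
        _count_in_span(reads_treated, chrom, start, end), len(reads_treated),
        _count_in_span(reads_control, chrom, start, end), len(reads_control),
    )
    return value


def _count_in_span(reads: Sequence[ReadAlignment], chrom: str, start: int, end: int) -> int:
    return sum(1 for r in reads if r.chrom == chrom and start <= r.five_prime < end)


def attach_normalized_difference(
    calls: list[DifferentialCall],
    reads_treated: Sequence[ReadAlignment],
    reads_control: Sequence[ReadAlignment],
    chrom_sizes: dict[str, int],
) -> list[DifferentialCall]:
    """Fill normalized_difference for every call (vectorised over spans)."""
    if len(reads_treated) == 0 or len(reads_control) == 0:
        raise ValueError("library sizes must be > 0")
    pos_t = five_prime_positions(reads_treated, chrom_sizes)
    pos_c = five_prime_positions(reads_control, chrom_sizes)

    def count(pos, chrom, s, e):
        d = pos.get(chrom)
        if d is None:
            return 0
        p = d["all"]
        return int(np.searchsorted(p, e) - np.searchsorted(p, s))

    for call in calls:
        chrom, s, e = call.span
        value, degenerate = normalized_difference_counts(
            count(pos_t, chrom, s, e), len(reads_treated),
            count(pos_c, chrom, s, e), len(reads_control),
        )
        call.normalized_difference = value
        call.normalized_difference_degenerate = degenerate
    return calls


def global_methylation_summary(calls: list[DifferentialCall]) -> dict:
    """Totals per label plus a per-chromosome breakdown.

    ``n_shared`` counts shared pairs once, via the treated side.  The
    ``global_hypomethylation`` flag is set when hypo calls outnumber
    hyper calls.
    """
    n_hyper = sum(1 for c in calls if c.label == HYPER)
    n_hypo = sum(1 for c in calls if c.label == HYPO)
    n_shared = sum(1 for c in calls if c.label == SHARED and c.sample == "treated")
    per_chrom: dict[str, dict[str, int]] = {}
    for c in calls:
        if c.label == SHARED and c.sample != "treated":
            continue
        chrom = c.span[0]
        d = per_chrom.setdefault(chrom, {HYPER: 0, HYPO: 0, SHARED: 0})
        d[c.label] += 1
    return {
        "n_hyper": n_hyper,
        "n_hypo": n_hypo,
        "n_shared": n_shared,
        "per_chromosome": per_chrom,
        "global_hypomethylation": n_hypo > n_hyper,
    }
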