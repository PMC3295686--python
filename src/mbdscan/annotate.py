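"""Genomic feature annotation of called peaks.

Peaks are assigned to one of four classes — promoter, gene body,
3'-flanking region, intergenic — using wide, strand-aware definitions:
the promoter is the 20 kbp upstream of the transcription start site, the
3'-flank the 20 kbp downstream of the transcription termination site, and
the gene body the full transcribed span (exons and introns, unioned over
transcripts).  These regions can overlap between neighbouring genes, so a
peak is classified by its largest overlap with each class's interval
union, with ties broken gene_body > promoter > three_prime_flank; a peak
touching none of them is intergenic.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneModel
from .peaks import Peak

DEFAULT_FLANK_SIZE = 20_000

GENE_BODY = "gene_body"
PROMOTER = "promoter"
THREE_PRIME_FLANK = "three_prime_flank"
INTERGENIC = "intergenic"
FEATURE_CLASSES = (GENE_BODY, PROMOTER, THREE_PRIME_FLANK, INTERGENIC)

# tie-break precedence among overlapping classes
_PRECEDENCE = (GENE_BODY, PROMOTER, THREE_PRIME_FLANK)


@dataclass
class AnnotatedPeak:
    peak: Peak
    feature_class: str
    nearest_gene: str | None
    distance_to_tss: int | None


def _merge(ivs: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if s >= e:
            continue
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    starts = np.array([s for s, _ in out], dtype=np.int64)
    ends = np.array([e for _, e in out], dtype=np.int64)
    return starts, ends


class FeatureIndex:
    """Per-chromosome merged interval unions for the three gene-linked classes,
    plus per-chromosome TSS lists for nearest-gene lookup."""

    def __init__(
        self,
        class_intervals: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]],
        tss_by_chrom: dict[str, list[tuple[int, str, str]]],
        flank_size: int,
    ) -> None:
        self.class_intervals = class_intervals
        # sorted (tss, gene_id, strand) per chromosome
        self.tss_by_chrom = {
            c: sorted(v) for c, v in tss_by_chrom.items()
        }
        self.flank_size = flank_size

    def overlap(self, chrom: str, start: int, end: int, feature_class: str) -> int:
        """Total bp of [start, end) covered by the class's interval union."""
        per_class = self.class_intervals.get(chrom)
        if per_class is None:
            return 0
        starts, ends = per_class[feature_class]
        if len(starts) == 0:
            return 0
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0
        return int(
            np.sum(np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start))
        )


def build_feature_index(
    gene_models: list[GeneModel],
    flank_size: int = DEFAULT_FLANK_SIZE,
    chrom_sizes: dict[str, int] | None = None,
) -> FeatureIndex:
    """Build strand-aware promoter / gene-body / 3'-flank interval unions.

    For a '+' gene the promoter is ``[tss - flank, tss)`` and the 3'-flank
    ``[tts, tts + flank)``; for a '-' gene (where tss > tts in genome
    coordinates) the promoter is ``[tss, tss + flank)`` and the 3'-flank
    ``[tts - flank, tts)``.  Intervals are clipped to chromosome bounds
    (to [0, inf) when chromosome sizes are not given).
    """
    if flank_size <= 0:
        raise ValueError("flank_size must be > 0")
    per_chrom: dict[str, dict[str, list[tuple[int, int]]]] = {}
    tss_by_chrom: dict[str, list[tuple[int, str, str]]] = {}
    for g in gene_models:
        if chrom_sizes is not None and g.chrom not in chrom_sizes:
            raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom!r}")
        limit = chrom_sizes[g.chrom] if chrom_sizes is not None else None
        lo, hi = g.span
        if g.strand == "+":
            promoter = (g.tss - flank_size, g.tss)
            flank3 = (g.tts, g.tts + flank_size)
        else:
            promoter = (g.tss, g.tss + flank_size)
            flank3 = (g.tts - flank_size, g.tts)

        def clip(iv: tuple[int, int]) -> tuple[int, int]:
            s = max(0, iv[0])
            e = iv[1] if limit is None else min(iv[1], limit)
            return s, e

        d = per_chrom.setdefault(g.chrom, {GENE_BODY: [], PROMOTER: [],
                                           THREE_PRIME_FLANK: []})
        d[GENE_BODY].append(clip((lo, hi)))
        d[PROMOTER].append(clip(promoter))
        d[THREE_PRIME_FLANK].append(clip(flank3))
        tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id, g.strand))

    merged = {
        chrom: {cls: _merge(ivs) for cls, ivs in classes.items()}
        for chrom, classes in per_chrom.items()
    }
    return FeatureIndex(merged, tss_by_chrom, flank_size)


def _nearest_gene(
    index: FeatureIndex, chrom: str, midpoint: float
) -> tuple[str | None, int | None]:
    entries = index.tss_by_chrom.get(chrom)
    if not entries:
        return None, None
    tss_values = [t for t, _, _ in entries]
    i = bisect_left(tss_values, midpoint)
    best: tuple[float, str, int, str] | None = None  # (|d|, gene_id, tss, strand)
    for j in (i - 1, i, i + 1):
        if 0 <= j < len(entries):
            tss, gene_id, strand = entries[j]
            cand = (abs(midpoint - tss), gene_id, tss, strand)
            if best is None or cand[:2] < best[:2]:  # ties -> smallest gene_id
                best = cand
    _, gene_id, tss, strand = best
    signed = midpoint - tss if strand == "+" else tss - midpoint
    return gene_id, int(round(signed))


def annotate_peak(peak: Peak, index: FeatureIndex) -> AnnotatedPeak:
    """Classify one peak by largest class overlap; record the nearest TSS.

    ``distance_to_tss`` is signed in the nearest gene's orientation:
    negative upstream of its TSS, positive downstream.
    """
    overlaps = {
        cls: index.overlap(peak.chrom, peak.start, peak.end, cls)
        for cls in _PRECEDENCE
    }
    best = max(overlaps.values())
    if best == 0:
        cls = INTERGENIC
    else:
        cls = next(c for c in _PRECEDENCE if overlaps[c] == best)
    midpoint = (peak.start + peak.end) / 2.0
    gene_id, dist = _nearest_gene(index, peak.chrom, midpoint)
    return AnnotatedPeak(peak, cls, gene_id, dist)


def annotate_peaks(peaks: list[Peak], index: FeatureIndex) -> list[AnnotatedPeak]:
    return [annotate_peak(p, index) for p in peaks]


def feature_proportions(annotated_peaks: list[AnnotatedPeak]) -> dict:
    """Fractions of peaks per feature class.

    Returns the four-way split plus the three-way grouping where promoter
    and 3'-flank form one "regulatory" class.  Empty input yields all-zero
    fractions and n = 0.
    """
    n = len(annotated_peaks)
    counts = {cls: 0 for cls in FEATURE_CLASSES}
    for ap in annotated_peaks:
        counts[ap.feature_class] += 1
    fractions = {cls: (counts[cls] / n if n else 0.0) for cls in FEATURE_CLASSES}
    grouped = {
        GENE_BODY: fractions[GENE_BODY],
        "regulatory": fractions[PROMOTER] + fractions[THREE_PRIME_FLANK],
        INTERGENIC: fractions[INTERGENIC],
    }
    return {"n": n, "fractions": fractions, "grouped": grouped}


def chromosomal_distribution(
    peaks_by_sample: dict[str, list], chromosomes: list[str] | None = None
) -> pd.DataFrame:
    """Per-chromosome peak counts for two samples plus their ratio.

    ``peaks_by_sample`` maps sample name -> peaks (Peak or AnnotatedPeak);
    the first key is treated, the second control.  Chromosomes with zero
    peaks in both samples are included (with zeros) when ``chromosomes``
    is given.  The ratio column is treated/control, NaN-flagged as
    undefined where the control count is 0.
    """
    names = list(peaks_by_sample)
    if len(names) != 2:
        raise ValueError("expected exactly two samples (treated, control)")

    def chrom_of(p):
        return p.peak.chrom if hasattr(p, "peak") else p.chrom

    counts: dict[str, dict[str, int]] = {}
    for name in names:
        for p in peaks_by_sample[name]:
            counts.setdefault(chrom_of(p), {n: 0 for n in names})[name] += 1
    if chromosomes is None:
        chromosomes = sorted(counts)
    else:
        for c in counts:
            if c not in chromosomes:
                raise ValueError(f"peak on chromosome {c!r} outside the given list")
    rows = []
    t_name, c_name = names
    for chrom in chromosomes:
        n_t = counts.get(chrom, {}).get(t_name, 0)
        n_c = counts.get(chrom, {}).get(c_name, 0)
        rows.append(
            {
                "chrom": chrom,
                f"n_{t_name}": n_t,
                f"n_{c_name}": n_c,
                "ratio": (n_t / n_c) if n_c else np.nan,
                "ratio_undefined": n_c == 0,
            }
        )
    return pd.DataFrame(rows).set_index("chrom")
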