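"""Readers and writers for the formats the pipeline touches.

Every coordinate inside the package is 0-based half-open (BED native).
Conversion to and from 1-based closed coordinates happens only at the GTF
boundary.  Reads are stranded BED6 records; gene models come from GTF 2.2
or BED12; gene sets from GMT; peak tables are TSV with a companion BED6.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A record in an input file violates the format contract."""


class ReadAlignment(NamedTuple):
    """One mapped fragment: chromosome, 0-based half-open span, strand."""

    chrom: str
    start: int
    end: int
    strand: str

    @property
    def five_prime(self) -> int:
        """5'-most genomic coordinate: start on '+', end - 1 on '-'."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GeneModel:
    """A gene as the union of its transcripts.

    ``tss`` and ``tts`` are genome coordinates chosen so that ``tss`` is the
    transcription start: on '+' the gene span is ``[tss, tts)`` with
    ``tss < tts``; on '-' the span is ``[tts, tss)`` with ``tts < tss``
    (``tss`` equals the half-open end of the span).  ``exons`` are merged,
    non-overlapping 0-based half-open intervals within the span.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.strand == "+" and not self.tss < self.tts:
            raise ValueError(f"gene {self.gene_id}: + strand requires tss < tts")
        if self.strand == "-" and not self.tts < self.tss:
            raise ValueError(f"gene {self.gene_id}: - strand requires tts < tss")

    @property
    def span(self) -> tuple[int, int]:
        return min(self.tss, self.tts), max(self.tss, self.tts)


@dataclass
class GeneSet:
    set_id: str
    description: str
    members: frozenset[str]


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Read a two-column ``<chrom>\\t<length>`` file (UCSC chrom.sizes)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}: line {i}: expected '<chrom> <length>'")
            try:
                length = int(parts[1])
            except ValueError as exc:
                raise FormatError(f"{path}: line {i}: length not an integer") from exc
            if length <= 0:
                raise FormatError(f"{path}: line {i}: non-positive chromosome length")
            sizes[parts[0]] = length
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def read_bed_reads(path: str | os.PathLike) -> list[ReadAlignment]:
    """Read stranded fragments from a BED6 file.

    Strand must be '+' or '-'; '.' is rejected because downstream peak
    refinement needs read orientation.  Coordinates are kept as-is
    (BED is already 0-based half-open).  Order is preserved.
    """
    reads: list[ReadAlignment] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}: line {i}: expected >= 6 BED columns")
            chrom, start_s, end_s, _name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}: line {i}: non-integer coordinates") from exc
            if not start < end:
                raise FormatError(f"{path}: line {i}: start must be < end")
            if strand not in ("+", "-"):
                raise FormatError(
                    f"{path}: line {i}: strand {strand!r} not allowed "
                    "(reads must be '+' or '-')"
                )
            reads.append(ReadAlignment(chrom, start, end, strand))
    return reads


def write_bed_reads(reads: Iterable[ReadAlignment], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tread_{i}\t0\t{r.strand}\n")


def read_bed_intervals(path: str | os.PathLike) -> list[tuple[str, int, int]]:
    """Read unstranded intervals (>= 3 BED columns); strand, if any, ignored."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {i}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {i}: non-integer coordinates") from exc
            if not start < end:
                raise FormatError(f"{path}: line {i}: start must be < end")
            out.append((fields[0], start, end))
    return out


def write_bed_intervals(
    intervals: Sequence[tuple[str, int, int]],
    path: str | os.PathLike,
    name_prefix: str = "region",
) -> None:
    """Write unstranded intervals as BED6 (score 0, strand '.'), sorted."""
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(
            sorted(intervals, key=lambda iv: (iv[0], iv[1], iv[2]))
        ):
            fh.write(f"{chrom}\t{start}\t{end}\t{name_prefix}_{i}\t0\t.\n")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _models_from_exons(
    exons_by_gene: dict[str, list[tuple[str, str, int, int]]]
) -> list[GeneModel]:
    """Assemble one GeneModel per gene from (chrom, strand, start, end) exons."""
    models = []
    for gene_id, exons in exons_by_gene.items():
        chroms = {e[0] for e in exons}
        strands = {e[1] for e in exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise FormatError(
                f"gene {gene_id}: exons span multiple chromosomes or strands"
            )
        chrom, strand = exons[0][0], exons[0][1]
        merged = _merge_intervals((s, e) for _, _, s, e in exons)
        lo, hi = merged[0][0], merged[-1][1]
        tss, tts = (lo, hi) if strand == "+" else (hi, lo)
        models.append(GeneModel(gene_id, chrom, strand, tss, tts, merged))
    return models


def _read_gtf(path: str | os.PathLike) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons_by_gene: dict[str, list[tuple[str, str, int, int]]] = {}
    for feat in db.features_of_type("exon"):
        gene_ids = feat.attributes.get("gene_id")
        if not gene_ids:
            raise FormatError(f"{path}: exon at {feat.seqid}:{feat.start} has no gene_id")
        if feat.strand not in ("+", "-"):
            raise FormatError(
                f"{path}: exon of gene {gene_ids[0]} lacks a +/- strand"
            )
        # GTF is 1-based closed; internal storage is 0-based half-open.
        exons_by_gene.setdefault(gene_ids[0], []).append(
            (feat.seqid, feat.strand, feat.start - 1, feat.end)
        )
    return _models_from_exons(exons_by_gene)


def _read_bed12(path: str | os.PathLike) -> list[GeneModel]:
    exons_by_gene: dict[str, list[tuple[str, str, int, int]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}: line {i}: expected 12 BED columns")
            chrom, start, end, name, _score, strand = (
                f[0], int(f[1]), int(f[2]), f[3], f[4], f[5],
            )
            if strand not in ("+", "-"):
                raise FormatError(f"{path}: line {i}: strand {strand!r} not allowed")
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(f"{path}: line {i}: block count mismatch")
            for size, off in zip(sizes, offsets):
                es, ee = start + off, start + off + size
                if not (start <= es < ee <= end):
                    raise FormatError(f"{path}: line {i}: block outside record span")
                exons_by_gene.setdefault(name, []).append((chrom, strand, es, ee))
    return _models_from_exons(exons_by_gene)


def read_gene_models(path: str | os.PathLike, format: str = "gtf") -> list[GeneModel]:
    """Read gene models from GTF 2.2 or BED12.

    Exons are grouped by gene_id (GTF) or record name (BED12), merged across
    transcripts, and the TSS/TTS taken from the extreme coordinates of the
    union respecting strand.
    """
    if format == "gtf":
        return _read_gtf(path)
    if format == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown gene model format {format!r} (expected gtf or bed12)")


def write_gtf(models: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models back to GTF 2.2 (one exon line per merged exon)."""
    with open(path, "w") as fh:
        for m in models:
            for j, (s, e) in enumerate(m.exons):
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.t1";'
                fh.write(
                    f"{m.chrom}\tmbdscan\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | os.PathLike) -> list[GeneSet]:
    """Read gene sets: tab-separated, col 1 name, col 2 description, rest genes."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: line {i}: expected name, description, genes")
            members = frozenset(g for g in fields[2:] if g)
            sets.append(GeneSet(fields[0], fields[1], members))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in sets:
            genes = "\t".join(sorted(s.members))
            fh.write(f"{s.set_id}\t{s.description}\t{genes}\n" if genes
                     else f"{s.set_id}\t{s.description}\n")


# ---------------------------------------------------------------------------
# Peak tables
# ---------------------------------------------------------------------------

PEAK_TABLE_COLUMNS = [
    "chrom", "start", "end", "read_count", "fdr", "normalized_difference",
    "wilcoxon_p", "feature_class", "nearest_gene", "differential_label",
]


def bed_score_from_fdr(fdr: float) -> int:
    """BED score = round(-10 log10 FDR), capped at 1000; FDR 1 -> 0, FDR 0 -> 1000."""
    if fdr <= 0:
        return 1000
    return min(1000, int(round(-10.0 * math.log10(fdr))))


def write_peak_table(peaks: pd.DataFrame, path_prefix: str | os.PathLike) -> tuple[str, str]:
    """Write an annotated peak table as ``<prefix>.tsv`` plus ``<prefix>.bed``.

    The TSV carries exactly :data:`PEAK_TABLE_COLUMNS` in that order, floats
    serialised with 6 significant digits.  The BED6 companion scores each
    peak as round(-10*log10(fdr)) capped at 1000.
    """
    prefix = str(path_prefix)
    tsv_path, bed_path = prefix + ".tsv", prefix + ".bed"
    frame = peaks.copy()
    for col in PEAK_TABLE_COLUMNS:
        if col not in frame.columns:
            frame[col] = np.nan
    frame = frame[PEAK_TABLE_COLUMNS]
    frame.to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    with open(bed_path, "w") as fh:
        for i, row in enumerate(frame.itertuples(index=False)):
            fdr = row.fdr if np.isfinite(row.fdr) else 1.0
            fh.write(
                f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\tpeak_{i}"
                f"\t{bed_score_from_fdr(fdr)}\t.\n"
            )
    return tsv_path, bed_path


def read_peak_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a peak TSV written by :func:`write_peak_table`."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing peak table columns {missing}")
    return frame[PEAK_TABLE_COLUMNS]
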