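"""Synthetic MBP-capture sequencing data with known ground truth.

The generator emulates the statistical structure the pipeline assumes:
a small multi-chromosome genome carrying planted methylated intervals,
random fragmentation into 50-350 bp pieces, strand-aware placement, and
methyl-binding-protein capture modelled as a per-fragment acceptance
probability (a fragment touching a methylated interval is kept with
probability ``enrichment_factor`` times the background probability).  A
two-condition contrast where the treated sample retains only a subset of
the control's methylated intervals emulates global hypomethylation.

Capture chemistry (salt elution, CpG density) is deliberately not
modelled: downstream stages only consume the count enrichment structure.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import ReadAlignment, read_bed_intervals, write_bed_intervals

TREATED = "treated"
CONTROL = "control"


class PlacementError(RuntimeError):
    """Non-overlapping region placement failed after bounded retries."""


def _merge(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    for chrom, s, e in sorted(intervals):
        if out and out[-1][0] == chrom and s <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], e))
        else:
            out.append((chrom, s, e))
    return out


@dataclass
class MethylationLandscape:
    """Ground-truth genome: chromosome sizes plus methylated intervals per condition.

    Intervals are 0-based half-open, merged and sorted within each condition.
    """

    chrom_sizes: dict[str, int]
    methylated_regions: dict[str, list[tuple[str, int, int]]]
    condition_names: tuple[str, str] = (TREATED, CONTROL)

    def __post_init__(self) -> None:
        for cond, regions in self.methylated_regions.items():
            for chrom, s, e in regions:
                if chrom not in self.chrom_sizes:
                    raise ValueError(f"{cond}: interval on unknown chromosome {chrom}")
                if not (0 <= s < e <= self.chrom_sizes[chrom]):
                    raise ValueError(
                        f"{cond}: interval {chrom}:{s}-{e} outside chromosome bounds"
                    )
            self.methylated_regions[cond] = _merge(regions)

    def regions(self, condition: str) -> list[tuple[str, int, int]]:
        return self.methylated_regions[condition]


@dataclass
class SimulationConfig:
    """Knobs of the capture-sequencing generator.

    enrichment_factor
        Capture probability of a fragment overlapping a methylated interval
        relative to background; >= 1.  1 means no enrichment (pure background).
    n_reads
        Exact number of emitted fragments; 0 yields an empty read set.
    fragment_length_min/max
        Uniform fragment length bounds in bp (defaults 50/350, the sonication
        range of standard fragment libraries).
    mean_background_coverage
        Alternative sizing: if ``n_reads`` is None, the read count is chosen
        so mean genome coverage equals this fold value.
    """

    enrichment_factor: float = 8.0
    n_reads: int | None = 100_000
    fragment_length_min: int = 50
    fragment_length_max: int = 350
    mean_background_coverage: float | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fragment_length_min < 1:
            raise ValueError("fragment_length_min must be >= 1")
        if self.fragment_length_min > self.fragment_length_max:
            raise ValueError("fragment_length_min must be <= fragment_length_max")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if self.n_reads is None and self.mean_background_coverage is None:
            raise ValueError("give n_reads or mean_background_coverage")

    def resolve_n_reads(self, genome_length: int) -> int:
        if self.n_reads is not None:
            return int(self.n_reads)
        mean_len = 0.5 * (self.fragment_length_min + self.fragment_length_max)
        return int(round(self.mean_background_coverage * genome_length / mean_len))


def simulate_landscape(
    chrom_sizes: dict[str, int],
    n_regions_control: int,
    fraction_retained_in_treated: float,
    region_length_range: tuple[int, int] = (500, 2000),
    rng_seed: int = 0,
    max_tries: int = 1000,
    min_gap: int = 0,
) -> MethylationLandscape:
    """Plant non-overlapping methylated intervals; treated keeps a random subset.

    Control receives ``n_regions_control`` intervals with lengths uniform in
    ``region_length_range``, placed uniformly without overlap (chromosomes
    weighted by length) and separated by at least ``min_gap`` bp.  The
    treated condition retains a uniformly sampled subset of size
    ``round(fraction_retained_in_treated * n_regions_control)`` — the
    global-hypomethylation contrast.  Deterministic for a fixed seed.
    """
    if n_regions_control < 0:
        raise ValueError("n_regions_control must be >= 0")
    if not 0.0 <= fraction_retained_in_treated <= 1.0:
        raise ValueError("fraction_retained_in_treated must be in [0, 1]")
    lo, hi = region_length_range
    if not 1 <= lo <= hi:
        raise ValueError("region_length_range must satisfy 1 <= min <= max")
    rng = np.random.default_rng(rng_seed)
    chroms = list(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum() if lengths.sum() > 0 else None

    placed: list[tuple[str, int, int]] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for _ in range(n_regions_control):
        for attempt in range(max_tries):
            ci = int(rng.choice(len(chroms), p=weights))
            chrom = chroms[ci]
            length = int(rng.integers(lo, hi + 1))
            if length > chrom_sizes[chrom]:
                continue
            start = int(rng.integers(0, chrom_sizes[chrom] - length + 1))
            end = start + length
            if all(e + min_gap <= start or s >= end + min_gap
                   for s, e in occupied[chrom]):
                occupied[chrom].append((start, end))
                placed.append((chrom, start, end))
                break
        else:
            raise PlacementError(
                f"could not place a non-overlapping region on {chrom} "
                f"after {max_tries} tries"
            )

    n_keep = int(round(fraction_retained_in_treated * n_regions_control))
    keep_idx = rng.choice(len(placed), size=n_keep, replace=False) if placed else []
    treated = [placed[i] for i in sorted(keep_idx)]
    return MethylationLandscape(
        chrom_sizes=dict(chrom_sizes),
        methylated_regions={TREATED: treated, CONTROL: list(placed)},
    )


def _region_arrays(
    regions: list[tuple[str, int, int]], chroms: list[str]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in chroms:
        ivs = sorted((s, e) for c, s, e in regions if c == chrom)
        starts = np.array([s for s, _ in ivs], dtype=np.int64)
        ends = np.array([e for _, e in ivs], dtype=np.int64)
        by_chrom[chrom] = (starts, ends)
    return by_chrom


def _overlaps_any(
    frag_start: np.ndarray, frag_end: np.ndarray,
    starts: np.ndarray, ends: np.ndarray,
) -> np.ndarray:
    """Vectorised >= 1 bp intersection test against merged sorted intervals."""
    if len(starts) == 0:
        return np.zeros(len(frag_start), dtype=bool)
    idx = np.searchsorted(ends, frag_start, side="right")
    hit = idx < len(starts)
    hit[hit] = starts[idx[hit]] < frag_end[hit]
    return hit


def simulate_reads(
    landscape: MethylationLandscape,
    condition: str,
    config: SimulationConfig,
) -> list[ReadAlignment]:
    """Draw captured fragments for one condition.

    Fragment starts are uniform over the genome, lengths uniform on the
    configured range (truncated at the chromosome end), strands uniform.
    A fragment intersecting any methylated interval of the condition is
    accepted with probability 1; background fragments with probability
    ``1 / enrichment_factor`` — so the expected read density ratio inside
    versus outside methylated intervals is exactly ``enrichment_factor``.
    Exactly the resolved number of reads is emitted (rejection sampling
    repeats until the target is met).  Deterministic for a fixed seed.
    """
    if condition not in landscape.condition_names:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of "
            f"{landscape.condition_names}"
        )
    chroms = list(landscape.chrom_sizes)
    if not chroms:
        raise ValueError("empty genome: no chromosomes")
    sizes = np.array([landscape.chrom_sizes[c] for c in chroms], dtype=np.int64)
    genome_len = int(sizes.sum())
    n_target = config.resolve_n_reads(genome_len)
    if n_target == 0:
        return []

    regions = _region_arrays(landscape.regions(condition), chroms)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    accept_bg = 1.0 / config.enrichment_factor
    rng = np.random.default_rng(config.rng_seed)

    out_chrom: list[np.ndarray] = []
    out_start: list[np.ndarray] = []
    out_end: list[np.ndarray] = []
    out_strand: list[np.ndarray] = []
    n_have = 0
    # expected acceptance rate >= accept_bg; batch accordingly
    batch = int(min(4_000_000, max(10_000, 1.2 * n_target / accept_bg)))
    while n_have < n_target:
        gpos = rng.integers(0, genome_len, size=batch)
        ci = np.searchsorted(offsets, gpos, side="right") - 1
        start = gpos - offsets[ci]
        length = rng.integers(
            config.fragment_length_min, config.fragment_length_max + 1, size=batch
        )
        end = np.minimum(start + length, sizes[ci])
        strand = rng.integers(0, 2, size=batch)  # 0 -> '+', 1 -> '-'
        u = rng.random(size=batch)

        meth = np.zeros(batch, dtype=bool)
        for k, chrom in enumerate(chroms):
            sel = ci == k
            if sel.any():
                starts_k, ends_k = regions[chrom]
                meth[sel] = _overlaps_any(start[sel], end[sel], starts_k, ends_k)
        accepted = meth | (u < accept_bg)
        out_chrom.append(ci[accepted])
        out_start.append(start[accepted])
        out_end.append(end[accepted])
        out_strand.append(strand[accepted])
        n_have += int(accepted.sum())

    ci = np.concatenate(out_chrom)[:n_target]
    start = np.concatenate(out_start)[:n_target]
    end = np.concatenate(out_end)[:n_target]
    strand = np.concatenate(out_strand)[:n_target]
    return [
        ReadAlignment(chroms[c], int(s), int(e), "+" if st == 0 else "-")
        for c, s, e, st in zip(ci, start, end, strand)
    ]


def write_truth(landscape: MethylationLandscape, path: str | os.PathLike) -> dict[str, str]:
    """Write one BED6 truth file per condition under ``path`` (a directory).

    Returns a condition -> file path map.  Re-reading the files with
    :func:`read_truth` reproduces the landscape's interval sets exactly.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for cond in landscape.condition_names:
        p = outdir / f"truth_{cond}.bed"
        write_bed_intervals(landscape.regions(cond), p, name_prefix=cond)
        files[cond] = str(p)
    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom, length in landscape.chrom_sizes.items():
            fh.write(f"{chrom}\t{length}\n")
    return files


def read_truth(path: str | os.PathLike) -> MethylationLandscape:
    """Inverse of :func:`write_truth`."""
    from .io import read_chrom_sizes

    outdir = Path(path)
    sizes = read_chrom_sizes(outdir / "chrom.sizes")
    regions = {
        cond: read_bed_intervals(outdir / f"truth_{cond}.bed")
        for cond in (TREATED, CONTROL)
    }
    return MethylationLandscape(chrom_sizes=sizes, methylated_regions=regions)


def write_config_echo(config: SimulationConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "enrichment_factor": config.enrichment_factor,
                "n_reads": config.n_reads,
                "fragment_length_min": config.fragment_length_min,
                "fragment_length_max": config.fragment_length_max,
                "mean_background_coverage": config.mean_background_coverage,
                "rng_seed": config.rng_seed,
            },
            fh,
            indent=2,
        )
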