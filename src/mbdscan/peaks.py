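"""Window-based peak calling against a negative-binomial background.

The caller follows four steps:

1. estimate the null distribution of the background signal — a negative
   binomial fitted (method of moments) to read counts of low-coverage
   windows;
2. scan fixed-width windows and flag those whose count is unlikely under
   the null, using an empirical FDR statistic: for a count ``c``,
   ``FDR(c) = P_null(C >= c) / (observed fraction of windows with count >= c)``;
3. merge overlapping candidate windows into peaks;
4. refine peaks using the spatial separation of forward and reverse read
   5' positions (one-sided Wilcoxon rank-sum), since true enrichment of
   double-stranded fragments places forward reads to the left of reverse
   reads within a peak.

Reads are assigned to windows by their 5'-most coordinate, which makes the
non-overlapping tiling a partition of the reads (counts are conserved).

A statsmodels-style front end wraps the steps: ``MBDScan(reads,
chrom_sizes).fit()`` returns a :class:`PeakCallingResult` carrying the
fitted null, the FDR table, the peaks and a ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from math import comb, erf, sqrt
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ReadAlignment

logger = logging.getLogger("mbdscan")

DEFAULT_WINDOW_SIZE = 300
DEFAULT_STEP = 100  # window_size / 3: sub-window resolution at modest cost
DEFAULT_MAX_FDR = 0.01
DEFAULT_LOW_COVERAGE_QUANTILE = 0.90


# ---------------------------------------------------------------------------
# Window counting
# ---------------------------------------------------------------------------

@dataclass
class WindowCountTrack:
    """Per-chromosome read counts in fixed-width windows tiled from 0."""

    window_size: int
    step: int
    chrom_sizes: dict[str, int]
    # chrom -> (window start array, count array)
    windows: dict[str, tuple[np.ndarray, np.ndarray]]

    @property
    def n_windows(self) -> int:
        return sum(len(starts) for starts, _ in self.windows.values())

    def all_counts(self) -> np.ndarray:
        if not self.windows:
            return np.zeros(0, dtype=np.int64)
        return np.concatenate([c for _, c in self.windows.values()])

    def window_end(self, chrom: str, start: int) -> int:
        return min(start + self.window_size, self.chrom_sizes[chrom])


def five_prime_positions(
    reads: Iterable[ReadAlignment], chrom_sizes: dict[str, int]
) -> dict[str, dict[str, np.ndarray]]:
    """Sorted 5' coordinates per chromosome, total and per strand."""
    by_chrom: dict[str, dict[str, list[int]]] = {}
    for r in reads:
        if r.chrom not in chrom_sizes:
            raise ValueError(f"read on unknown chromosome {r.chrom!r}")
        d = by_chrom.setdefault(r.chrom, {"+": [], "-": []})
        d[r.strand].append(r.five_prime)
    out: dict[str, dict[str, np.ndarray]] = {}
    for chrom, d in by_chrom.items():
        fwd = np.sort(np.array(d["+"], dtype=np.int64))
        rev = np.sort(np.array(d["-"], dtype=np.int64))
        out[chrom] = {"+": fwd, "-": rev, "all": np.sort(np.concatenate([fwd, rev]))}
    return out


def count_windows(
    reads: Sequence[ReadAlignment],
    chrom_sizes: dict[str, int],
    window_size: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_STEP,
) -> WindowCountTrack:
    """Count read 5' ends in windows tiled from 0 with the given step.

    Every chromosome is tiled ``0, step, 2*step, ...``; the last partial
    window is kept.  A read is counted in every window containing its
    5'-most coordinate (start for '+', end-1 for '-').
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if not 1 <= step <= window_size:
        raise ValueError("step must satisfy 1 <= step <= window_size")
    pos = five_prime_positions(reads, chrom_sizes)
    windows: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, length in chrom_sizes.items():
        starts = np.arange(0, length, step, dtype=np.int64)
        p = pos.get(chrom, {}).get("all", np.zeros(0, dtype=np.int64))
        ends = np.minimum(starts + window_size, length)
        counts = np.searchsorted(p, ends) - np.searchsorted(p, starts)
        windows[chrom] = (starts, counts.astype(np.int64))
    return WindowCountTrack(window_size, step, dict(chrom_sizes), windows)


# ---------------------------------------------------------------------------
# Null model
# ---------------------------------------------------------------------------

@dataclass
class NullModel:
    """Negative-binomial background fitted on low-coverage windows.

    Parametrised by mean ``mu`` and dispersion ``k`` with variance
    ``mu + mu**2 / k``.  When the low-coverage counts show no
    overdispersion (variance <= mean) the model degrades to Poisson(mu)
    (``k`` is None).  ``mu == 0`` marks a degenerate, all-zero track: any
    window with a single read is then called.
    """

    mu: float
    k: float | None
    low_coverage_cutoff: float
    n_windows_used: int

    @property
    def is_poisson(self) -> bool:
        return self.k is None

    @property
    def degenerate(self) -> bool:
        return self.mu == 0.0

    def _dist(self):
        if self.is_poisson:
            return stats.poisson(self.mu)
        p = self.k / (self.k + self.mu)
        return stats.nbinom(self.k, p)

    def sf(self, c: np.ndarray | float) -> np.ndarray | float:
        """Upper tail P(C >= c)."""
        c = np.asarray(c)
        if self.degenerate:
            return np.where(c <= 0, 1.0, 0.0)
        return self._dist().sf(c - 1)

    def pmf(self, c: np.ndarray | float) -> np.ndarray | float:
        c = np.asarray(c)
        if self.degenerate:
            return np.where(c == 0, 1.0, 0.0)
        return self._dist().pmf(c)

    def to_dict(self) -> dict:
        return {
            "family": "poisson" if self.is_poisson else "negative_binomial",
            "mu": self.mu,
            "k": self.k,
            "low_coverage_cutoff": self.low_coverage_cutoff,
            "n_windows_used": self.n_windows_used,
        }


def fit_null(
    track: WindowCountTrack,
    low_coverage_quantile: float = DEFAULT_LOW_COVERAGE_QUANTILE,
) -> NullModel:
    """Fit the background count model on low-coverage windows.

    "Low coverage" is quantified as window counts at or below the given
    quantile of all window counts.  The negative binomial is fitted by
    method of moments (mu = mean, k = mu^2 / (var - mu)); if the sample
    variance does not exceed the mean the fit degrades to Poisson(mu).
    """
    counts = track.all_counts()
    if counts.size == 0:
        raise ValueError("cannot fit a null model on an empty track")
    if not 0.0 < low_coverage_quantile <= 1.0:
        raise ValueError("low_coverage_quantile must be in (0, 1]")
    cutoff = float(np.quantile(counts, low_coverage_quantile))
    low = counts[counts <= cutoff]
    mu = float(low.mean())
    var = float(low.var(ddof=1)) if low.size > 1 else 0.0
    if mu == 0.0:
        logger.warning("all low-coverage window counts are zero; degenerate null")
        return NullModel(0.0, None, cutoff, int(low.size))
    if var <= mu:
        return NullModel(mu, None, cutoff, int(low.size))
    k = mu * mu / (var - mu)
    return NullModel(mu, k, cutoff, int(low.size))


# ---------------------------------------------------------------------------
# Empirical FDR
# ---------------------------------------------------------------------------

@dataclass
class FdrTable:
    """Empirical FDR per observed count value.

    ``raw`` holds the unregularised ratio expected-tail / observed-tail,
    clipped to [0, 1]; ``fdr`` its monotone regularisation (cumulative
    minimum over ascending counts, so FDR is non-increasing in the count).
    Counts never observed in the track are not tabulated.
    """

    counts: np.ndarray          # distinct observed counts, ascending
    raw: np.ndarray
    fdr: np.ndarray
    form: str = "tail"

    def lookup(self, c: np.ndarray) -> np.ndarray:
        """FDR for observed count values; NaN for untabulated counts."""
        c = np.asarray(c)
        idx = np.searchsorted(self.counts, c)
        idx_c = np.clip(idx, 0, len(self.counts) - 1)
        ok = self.counts[idx_c] == c
        out = np.where(ok, self.fdr[idx_c], np.nan)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"count": self.counts, "fdr_raw": self.raw, "fdr": self.fdr})


def compute_fdr_table(
    track: WindowCountTrack, null: NullModel, form: str = "tail"
) -> FdrTable:
    """Tabulate the empirical FDR statistic for every observed count.

    ``form="tail"`` (default) uses upper-tail fractions in both numerator
    and denominator: FDR(c) = P_null(C >= c) / frac_obs(count >= c).
    ``form="per_count"`` uses point masses instead:
    FDR(c) = P_null(C = c) / frac_obs(count = c).  Values are clipped to
    [0, 1] and then regularised to be non-increasing in c.
    """
    counts = track.all_counts()
    if counts.size == 0:
        raise ValueError("empty track")
    values, freq = np.unique(counts, return_counts=True)
    n = counts.size
    if form == "tail":
        obs = np.cumsum(freq[::-1])[::-1] / n     # frac(count >= c)
        expected = np.asarray(null.sf(values), dtype=float)
    elif form == "per_count":
        obs = freq / n
        expected = np.asarray(null.pmf(values), dtype=float)
    else:
        raise ValueError(f"unknown FDR form {form!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.clip(expected / obs, 0.0, 1.0)
    fdr = np.minimum.accumulate(raw)
    return FdrTable(values.astype(np.int64), raw, fdr, form=form)


# ---------------------------------------------------------------------------
# Scan / merge / refine
# ---------------------------------------------------------------------------

@dataclass
class CandidateWindow:
    chrom: str
    start: int
    end: int
    count: int
    fdr: float


@dataclass
class Peak:
    """A called region: merged candidate windows on one chromosome."""

    chrom: str
    start: int
    end: int
    read_count: int
    min_window_fdr: float
    wilcoxon_p: float = np.nan
    refined: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def scan_candidates(
    track: WindowCountTrack, fdr_table: FdrTable, max_fdr: float = DEFAULT_MAX_FDR
) -> list[CandidateWindow]:
    """Windows with at least one read and FDR(count) <= max_fdr."""
    if not 0.0 < max_fdr <= 1.0:
        raise ValueError("max_fdr must be in (0, 1]")
    out: list[CandidateWindow] = []
    for chrom in track.chrom_sizes:
        starts, counts = track.windows[chrom]
        fdrs = fdr_table.lookup(counts)
        keep = (counts >= 1) & np.isfinite(fdrs) & (fdrs <= max_fdr)
        for s, c, f in zip(starts[keep], counts[keep], fdrs[keep]):
            out.append(
                CandidateWindow(chrom, int(s), track.window_end(chrom, int(s)),
                                int(c), float(f))
            )
    return out


def merge_candidates(
    windows: Sequence[CandidateWindow],
    reads: Sequence[ReadAlignment] | None = None,
    chrom_sizes: dict[str, int] | None = None,
    merge_bookended: bool = False,
) -> list[Peak]:
    """Merge candidate windows that overlap by >= 1 bp into peaks.

    With ``merge_bookended`` (sensible when step == window size, where
    consecutive windows only touch), windows sharing a boundary also merge.
    The peak read_count is the number of reads whose 5' coordinate lies in
    the merged span (recounted from ``reads`` when given, else the max
    window count is used as a lower bound); min_window_fdr is the minimum
    over the merged windows.
    """
    pos = None
    if reads is not None:
        if chrom_sizes is None:
            chrom_sizes = {}
            for w in windows:
                chrom_sizes.setdefault(w.chrom, 0)
                chrom_sizes[w.chrom] = max(chrom_sizes[w.chrom], w.end)
            for r in reads:
                chrom_sizes.setdefault(r.chrom, 0)
                chrom_sizes[r.chrom] = max(chrom_sizes[r.chrom], r.end)
        pos = five_prime_positions(reads, chrom_sizes)

    by_chrom: dict[str, list[CandidateWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)

    peaks: list[Peak] = []
    for chrom in by_chrom:
        ws = sorted(by_chrom[chrom], key=lambda w: (w.start, w.end))
        cluster: list[CandidateWindow] = []

        def flush() -> None:
            if not cluster:
                return
            start = cluster[0].start
            end = max(w.end for w in cluster)
            if pos is not None:
                p = pos.get(chrom, {}).get("all", np.zeros(0, dtype=np.int64))
                count = int(np.searchsorted(p, end) - np.searchsorted(p, start))
            else:
                count = max(w.count for w in cluster)
            peaks.append(
                Peak(chrom, start, end, count, min(w.fdr for w in cluster))
            )

        for w in ws:
            if cluster:
                cur_end = max(c.end for c in cluster)
                joined = w.start < cur_end or (merge_bookended and w.start == cur_end)
                if not joined:
                    flush()
                    cluster = []
            cluster.append(w)
        flush()
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return peaks


# ---------------------------------------------------------------------------
# Strand-spatial refinement (one-sided Wilcoxon rank-sum)
# ---------------------------------------------------------------------------

EXACT_WILCOXON_LIMIT = 20  # exact permutation enumeration up to n + m = 20


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def _exact_rank_sum_p(ranks2: np.ndarray, n_fwd: int, w2_obs: int) -> float:
    """P(rank sum of a random n_fwd-subset <= observed), ties via midranks.

    ``ranks2`` are doubled midranks (integers); counts subsets by dynamic
    programming over (subset size, doubled rank sum).
    """
    total = int(ranks2.sum())
    # dp[j][s] = number of subsets of size j with doubled rank sum s
    dp = np.zeros((n_fwd + 1, total + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        dp[1:, r:] += dp[:-1, : total + 1 - r]
    n_le = float(dp[n_fwd, : min(w2_obs, total) + 1].sum())
    return n_le / comb(len(ranks2), n_fwd)


def rank_sum_left_p(forward: np.ndarray, reverse: np.ndarray) -> float:
    """One-sided p for "forward positions lie left of reverse positions".

    The statistic is the midrank sum of the forward positions in the pooled
    sample; small values support the alternative.  For n + m <= 20 the p-value
    is the exact permutation probability P(W <= W_obs); beyond that a normal
    approximation with tie-corrected variance and continuity correction is
    used.  Fewer than 2 observations on either side returns 1.0.
    """
    forward = np.asarray(forward, dtype=float)
    reverse = np.asarray(reverse, dtype=float)
    n, m = len(forward), len(reverse)
    if n < 2 or m < 2:
        return 1.0
    pooled = np.concatenate([forward, reverse])
    ranks = _midranks(pooled)
    w_obs = float(ranks[:n].sum())
    if n + m <= EXACT_WILCOXON_LIMIT:
        ranks2 = np.rint(2 * ranks).astype(np.int64)
        w2 = int(round(2 * w_obs))
        return _exact_rank_sum_p(ranks2, n, w2)
    # normal approximation, tie correction, continuity correction
    N = n + m
    mu_w = n * (N + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum()) / (N * (N - 1))
    var_w = n * m / 12.0 * ((N + 1) - tie_term)
    if var_w <= 0:
        return 0.5  # all positions identical: orientation uninformative
    z = (w_obs - mu_w + 0.5) / sqrt(var_w)
    return 0.5 * (1.0 + erf(z / sqrt(2.0)))


def refine_peaks(
    peaks: Sequence[Peak],
    reads: Sequence[ReadAlignment],
    chrom_sizes: dict[str, int],
    wilcoxon_alpha: float = 0.05,
    require_orientation: bool = False,
) -> list[Peak]:
    """Annotate peaks with the forward/reverse spatial separation p-value.

    Within each peak, forward-read 5' positions should precede reverse-read
    5' positions for genuine fragment pileups.  Peaks with fewer than two
    reads on either strand get p = 1.  By default the p-value is recorded
    and nothing is dropped; with ``require_orientation`` peaks whose p
    exceeds ``wilcoxon_alpha`` are removed.
    """
    pos = five_prime_positions(reads, chrom_sizes)
    out: list[Peak] = []
    for peak in peaks:
        d = pos.get(peak.chrom)
        if d is None:
            fwd = rev = np.zeros(0, dtype=np.int64)
        else:
            fwd = d["+"][np.searchsorted(d["+"], peak.start):
                         np.searchsorted(d["+"], peak.end)]
            rev = d["-"][np.searchsorted(d["-"], peak.start):
                         np.searchsorted(d["-"], peak.end)]
        p = rank_sum_left_p(fwd, rev)
        refined = replace(peak, wilcoxon_p=float(p), refined=True)
        if require_orientation and p > wilcoxon_alpha:
            continue
        out.append(refined)
    return out


# ---------------------------------------------------------------------------
# Composition and the model/results front end
# ---------------------------------------------------------------------------

def call_peaks(
    reads: Sequence[ReadAlignment],
    chrom_sizes: dict[str, int],
    window_size: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_STEP,
    max_fdr: float = DEFAULT_MAX_FDR,
    low_coverage_quantile: float = DEFAULT_LOW_COVERAGE_QUANTILE,
    fdr_form: str = "tail",
    merge_bookended: bool | None = None,
    require_orientation: bool = False,
    wilcoxon_alpha: float = 0.05,
) -> list[Peak]:
    """Run the four peak-calling steps and return refined peaks."""
    return MBDScan(
        reads, chrom_sizes,
        window_size=window_size, step=step, max_fdr=max_fdr,
        low_coverage_quantile=low_coverage_quantile, fdr_form=fdr_form,
        merge_bookended=merge_bookended,
        require_orientation=require_orientation, wilcoxon_alpha=wilcoxon_alpha,
    ).fit().peaks


class MBDScan:
    """Peak-calling model for methylated-DNA enrichment reads.

    Parameters
    ----------
    reads : sequence of ReadAlignment
        Mapped fragments (stranded).
    chrom_sizes : dict
        Chromosome name -> length in bp.
    window_size, step : int
        Scanning window width and stride (defaults 300 / 100 bp).
    max_fdr : float
        Maximum acceptable empirical FDR for a candidate window (default 1%).
    low_coverage_quantile : float
        Windows with counts at or below this quantile define the background
        used to fit the null (default 0.90).
    fdr_form : {"tail", "per_count"}
        Whether the FDR statistic compares upper-tail fractions (default)
        or per-count fractions.
    merge_bookended : bool, optional
        Merge windows sharing a boundary; defaults to True exactly when
        step == window_size (non-overlapping tiling).
    require_orientation : bool
        Drop peaks failing the strand-spatial Wilcoxon filter.
    """

    def __init__(
        self,
        reads: Sequence[ReadAlignment],
        chrom_sizes: dict[str, int],
        window_size: int = DEFAULT_WINDOW_SIZE,
        step: int = DEFAULT_STEP,
        max_fdr: float = DEFAULT_MAX_FDR,
        low_coverage_quantile: float = DEFAULT_LOW_COVERAGE_QUANTILE,
        fdr_form: str = "tail",
        merge_bookended: bool | None = None,
        require_orientation: bool = False,
        wilcoxon_alpha: float = 0.05,
    ) -> None:
        self.reads = reads
        self.chrom_sizes = dict(chrom_sizes)
        self.window_size = window_size
        self.step = step
        self.max_fdr = max_fdr
        self.low_coverage_quantile = low_coverage_quantile
        self.fdr_form = fdr_form
        self.merge_bookended = (
            step == window_size if merge_bookended is None else merge_bookended
        )
        self.require_orientation = require_orientation
        self.wilcoxon_alpha = wilcoxon_alpha

    def fit(self) -> "PeakCallingResult":
        track = count_windows(self.reads, self.chrom_sizes,
                              self.window_size, self.step)
        if len(self.reads) == 0:
            logger.info("no reads: empty peak list")
            return PeakCallingResult(self, track, None, None, [], [])
        null = fit_null(track, self.low_coverage_quantile)
        table = compute_fdr_table(track, null, form=self.fdr_form)
        candidates = scan_candidates(track, table, self.max_fdr)
        merged = merge_candidates(candidates, self.reads, self.chrom_sizes,
                                  merge_bookended=self.merge_bookended)
        peaks = refine_peaks(merged, self.reads, self.chrom_sizes,
                             wilcoxon_alpha=self.wilcoxon_alpha,
                             require_orientation=self.require_orientation)
        logger.info(
            "callpeaks: %d windows, cutoff %.3g, mu %.4g, k %s, "
            "%d candidates, %d peaks",
            track.n_windows, null.low_coverage_cutoff, null.mu,
            f"{null.k:.4g}" if null.k is not None else "Poisson",
            len(candidates), len(peaks),
        )
        return PeakCallingResult(self, track, null, table, candidates, peaks)


class PeakCallingResult:
    """Fit artefacts of :class:`MBDScan`: null model, FDR table, peaks."""

    def __init__(self, model, track, null_model, fdr_table, candidates, peaks):
        self.model = model
        self.track = track
        self.null_model = null_model
        self.fdr_table = fdr_table
        self.candidates = candidates
        self.peaks: list[Peak] = peaks

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": p.chrom, "start": p.start, "end": p.end,
                    "read_count": p.read_count, "fdr": p.min_window_fdr,
                    "wilcoxon_p": p.wilcoxon_p,
                }
                for p in self.peaks
            ],
            columns=["chrom", "start", "end", "read_count", "fdr", "wilcoxon_p"],
        )

    def summary(self) -> str:
        m = self.model
        lines = [
            "MBD-seq peak calling results",
            "=" * 44,
            f"{'reads':<28}{len(m.reads):>16,}",
            f"{'windows':<28}{self.track.n_windows:>16,}",
            f"{'window size (bp)':<28}{m.window_size:>16}",
            f"{'step (bp)':<28}{m.step:>16}",
            f"{'max FDR':<28}{m.max_fdr:>16g}",
        ]
        if self.null_model is not None:
            nm = self.null_model
            fam = "Poisson" if nm.is_poisson else "negative binomial"
            lines += [
                f"{'null family':<28}{fam:>16}",
                f"{'null mean mu':<28}{nm.mu:>16.4f}",
            ]
            if nm.k is not None:
                lines.append(f"{'null dispersion k':<28}{nm.k:>16.4f}")
            lines.append(
                f"{'low-coverage cutoff':<28}{nm.low_coverage_cutoff:>16.4g}"
            )
        lines += [
            f"{'candidate windows':<28}{len(self.candidates):>16,}",
            f"{'peaks':<28}{self.n_peaks:>16,}",
            "=" * 44,
        ]
        return "\n".join(lines)

    def plot_null_fit(self, ax=None, max_count: int | None = None):
        """Observed window-count histogram with the fitted null pmf overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        counts = self.track.all_counts()
        if max_count is None:
            max_count = int(np.quantile(counts, 0.999)) + 2
        xs = np.arange(0, max_count + 1)
        obs = np.bincount(np.minimum(counts, max_count), minlength=max_count + 1)
        ax.bar(xs, obs / counts.size, width=0.9, alpha=0.5, label="observed")
        if self.null_model is not None and not self.null_model.degenerate:
            ax.plot(xs, self.null_model.pmf(xs), "k.-", label="fitted null")
        ax.set_xlabel(f"reads per {self.track.window_size} bp window")
        ax.set_ylabel("fraction of windows")
        ax.legend()
        return ax
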