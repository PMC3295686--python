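"""Gene-set over-representation of peak-associated genes.

A focus list (e.g. genes whose promoters lost methylation) is tested
against user-supplied gene sets with a right-tailed Fisher's exact test:
the hypergeometric probability that a random draw of the focus size from
the gene universe hits the set at least as often as observed.  Raw
p-values are Benjamini-Hochberg adjusted across all tested sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Iterable, Sequence

from statsmodels.stats.multitest import multipletests

from .annotate import FEATURE_CLASSES, INTERGENIC
from .differential import LABELS, DifferentialCall
from .io import GeneSet


@dataclass
class EnrichmentResult:
    set_id: str
    description: str
    n_focus_in_set: int
    n_focus: int
    n_set: int
    n_universe: int
    p_value: float
    adjusted_p: float = float("nan")


def focus_genes(
    annotated_calls: Sequence[DifferentialCall],
    classes: Iterable[str],
    labels: Iterable[str],
    include_intergenic: bool = False,
) -> set[str]:
    """Unique nearest-gene ids of calls matching the class and label filters.

    Intergenic calls are excluded unless ``include_intergenic`` (their
    nearest gene is a distance annotation, not an assignment).
    """
    classes = set(classes)
    labels = set(labels)
    bad = classes - set(FEATURE_CLASSES)
    if bad:
        raise ValueError(f"unknown feature classes {sorted(bad)}")
    bad = labels - set(LABELS)
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}")
    out: set[str] = set()
    for call in annotated_calls:
        ap = call.peak
        cls = getattr(ap, "feature_class", None)
        if cls is None or call.label not in labels or cls not in classes:
            continue
        if cls == INTERGENIC and not include_intergenic:
            continue
        if ap.nearest_gene is not None:
            out.add(ap.nearest_gene)
    return out


def fisher_right_tail(
    n_focus_in_set: int, n_focus: int, n_set: int, n_universe: int
) -> float:
    """Right-tailed Fisher's exact test p-value, exact rational arithmetic.

    P(X >= n_focus_in_set) for X ~ Hypergeometric(N=n_universe, K=n_set,
    n=n_focus): the chance that a random focus list of the same size
    overlaps the set at least as much as observed.
    """
    if min(n_focus_in_set, n_focus, n_set, n_universe) < 0:
        raise ValueError("counts must be non-negative")
    if n_focus > n_universe or n_set > n_universe:
        raise ValueError("focus and set must fit inside the universe")
    if n_focus_in_set > min(n_focus, n_set):
        raise ValueError("overlap exceeds focus or set size")
    if n_focus_in_set < n_focus + n_set - n_universe:
        raise ValueError("overlap smaller than forced minimum")
    total = comb(n_universe, n_focus)
    tail = sum(
        Fraction(comb(n_set, x) * comb(n_universe - n_set, n_focus - x), total)
        for x in range(n_focus_in_set, min(n_focus, n_set) + 1)
    )
    return float(min(tail, Fraction(1)))


def enrich(
    focus: set[str],
    gene_sets: Sequence[GeneSet],
    universe: set[str],
) -> list[EnrichmentResult]:
    """Test every gene set for over-representation of the focus genes.

    Sets are intersected with the universe before testing; the focus must
    be a subset of the universe.  Results are BH-adjusted over all tested
    sets and sorted by raw p ascending (ties by set_id).
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not focus <= universe:
        raise ValueError("focus genes must be a subset of the universe")
    results: list[EnrichmentResult] = []
    for gs in gene_sets:
        members = gs.members & universe
        overlap = len(focus & members)
        p = fisher_right_tail(overlap, len(focus), len(members), len(universe))
        results.append(
            EnrichmentResult(gs.set_id, gs.description, overlap,
                             len(focus), len(members), len(universe), p)
        )
    if results:
        _, adj, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, a in zip(results, adj):
            r.adjusted_p = float(a)
    results.sort(key=lambda r: (r.p_value, r.set_id))
    return results
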