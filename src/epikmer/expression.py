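"""Nearest-gene assignment and paired expression-shift testing.

Each activated region is assigned to the gene with the closest TSS; the
expression of that gene set is then compared between conditions with a
paired two-sided Student's t-test on d_g = log2(treated_g + 1) −
log2(control_g + 1). The +1 pseudocount keeps zero-FPKM genes finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regions import DifferentialRegion

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ShiftTestResult:
    """Paired t-test outcome for one gene set's log2 expression shift."""

    n_genes: int
    mean_log2_shift: float
    t_statistic: float
    p_value: float
    transform: str = "paired t on log2(x+1), two-sided"
    degenerate: bool = False


def nearest_gene(
    regions: list[DifferentialRegion],
    tss: dict[str, list[tuple[int, str]]],
) -> dict[DifferentialRegion, str]:
    """Map each region to the gene with minimal |TSS − center|.

    ``tss`` maps contig -> list of (position, gene_id) sorted by position.
    Distance ties go to the smaller coordinate, then the lexicographically
    smaller gene id. Regions on contigs without any TSS are skipped with a
    logged warning.
    """
    if not any(tss.values()):
        raise ValueError("TSS annotation is empty")
    assignment: dict[DifferentialRegion, str] = {}
    arrays = {
        contig: (np.array([p for p, _ in entries]), [g for _, g in entries])
        for contig, entries in tss.items()
        if entries
    }
    for region in regions:
        contig = region.interval.contig
        if contig not in arrays:
            logger.warning(
                "region %s has no TSS on its contig; left unassigned", region.interval
            )
            continue
        positions, gene_ids = arrays[contig]
        i = int(np.searchsorted(positions, region.center))
        best: tuple[int, int, str] | None = None
        for j in (i - 1, i):
            if 0 <= j < len(positions):
                cand = (abs(int(positions[j]) - region.center), int(positions[j]),
                        gene_ids[j])
                if best is None or cand < best:
                    best = cand
        assignment[region] = best[2]
    return assignment


def expression_shift_test(
    gene_set: set[str],
    table: pd.DataFrame,
    alternative: str = "two-sided",
) -> ShiftTestResult:
    """Paired Student's t-test of log2(treated+1) − log2(control+1).

    If every paired difference is identical the statistic is undefined; a
    degenerate result with p = 1 is returned.
    """
    missing = set(gene_set) - set(table.index)
    if missing:
        raise ValueError(f"gene(s) not in expression table: {sorted(missing)}")
    if len(gene_set) < 2:
        raise ValueError("need at least 2 genes for a paired t-test")
    sub = table.loc[sorted(gene_set)]
    d = np.log2(sub["treated"].to_numpy() + 1.0) - np.log2(
        sub["control"].to_numpy() + 1.0
    )
    n = len(d)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return ShiftTestResult(
            n_genes=n,
            mean_log2_shift=mean,
            t_statistic=float("nan"),
            p_value=1.0,
            transform=f"paired t on log2(x+1), {alternative}",
            degenerate=True,
        )
    t = mean / (sd / np.sqrt(n))
    if alternative == "two-sided":
        p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    elif alternative == "greater":
        p = float(stats.t.sf(t, df=n - 1))
    elif alternative == "less":
        p = float(stats.t.cdf(t, df=n - 1))
    else:
        raise ValueError("alternative must be two-sided, greater, or less")
    return ShiftTestResult(
        n_genes=n,
        mean_log2_shift=mean,
        t_statistic=float(t),
        p_value=min(p, 1.0),
        transform=f"paired t on log2(x+1), {alternative}",
    )


def tss_index(annotation) -> dict[str, list[tuple[int, str]]]:
    """Build the sorted per-contig (TSS, gene_id) index from GeneRecords."""
    index: dict[str, list[tuple[int, str]]] = {}
    for gene in annotation:
        index.setdefault(gene.contig, []).append((gene.tss, gene.gene_id))
    for entries in index.values():
        entries.sort()
    return index
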