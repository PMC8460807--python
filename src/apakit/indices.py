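"""Sample- and gene-level derived scores.

The PA-machinery activity index summarizes expression of the cleavage and
polyadenylation apparatus (CPSF/CSTF and friends) as the per-sample median
of gene-wise z-scores. PSI-load is a per-sample global 3'UTR-shortening
index (median PSI over genes). Fold changes of PSI-load by driver-gene
mutation status, interval read counting for RIP-style binding quantification,
miRNA binding-site loss in the region between proximal and distal sites, and
the mRNA-protein concordance contrast complete the set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats import AlignedRead, BedInterval

log = logging.getLogger(__name__)


def pa_machinery_index(expression: pd.DataFrame,
                       gene_set: Iterable[str]) -> pd.Series:
    """Per-sample median z-score over the machinery gene set. Each gene is
    z-scored across samples (sd = 0 maps to z = 0)."""
    if expression.shape[1] < 2:
        raise ValueError("z-scores need at least 2 samples")
    gene_set = list(gene_set)
    present = [g for g in gene_set if g in expression.index]
    if not present:
        raise ValueError(f"no machinery genes in the matrix; missing: "
                         f"{sorted(gene_set)}")
    sub = expression.loc[present].astype(float)
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    z = sub.sub(mu, axis=0).div(sd.where(sd > 0), axis=0).fillna(0.0)
    z[sd == 0] = 0.0
    return z.median(axis=0).rename("pa_machinery_index")


def psi_load(psi: pd.DataFrame, statistic: str = "median") -> pd.Series:
    """Per-sample aggregate PSI over genes; NaN for samples with no defined
    PSI."""
    if psi.empty:
        raise ValueError("empty PSI matrix")
    if statistic == "median":
        return psi.median(axis=0, skipna=True).rename("psi_load")
    if statistic == "mean":
        return psi.mean(axis=0, skipna=True).rename("psi_load")
    raise ValueError(f"unknown statistic {statistic!r}")


def mutation_psi_fold_change(load: pd.Series, mutations: pd.DataFrame,
                             min_group: int = 5, fdr: float = 0.1,
                             fc_threshold: float = 0.1) -> pd.DataFrame:
    """Per driver gene: FC = median PSI-load of mutated over wildtype tumors
    with a two-sided Wilcoxon rank-sum p, BH across drivers; flagged when
    q < fdr and |FC - 1| > fc_threshold."""
    rows = []
    for gene in mutations.index:
        status = mutations.loc[gene]
        shared = [s for s in status.index if s in load.index]
        mut = load[[s for s in shared if status[s] == 1]].dropna()
        wt = load[[s for s in shared if status[s] == 0]].dropna()
        if len(mut) < min_group or len(wt) < min_group:
            continue
        wt_med = float(wt.median())
        if wt_med == 0:
            log.warning("wildtype median PSI-load is 0 for %s; skipped", gene)
            continue
        fc = float(mut.median()) / wt_med
        p = float(stats.ranksums(mut, wt).pvalue)
        rows.append({"gene": gene, "fc": fc, "p": p,
                     "n_mut": len(mut), "n_wt": len(wt)})
    out = pd.DataFrame(rows, columns=["gene", "fc", "p", "n_mut", "n_wt"])
    if out.empty:
        return out.set_index("gene")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["flagged"] = (out["q"] < fdr) & ((out["fc"] - 1).abs() > fc_threshold)
    return out.set_index("gene")


def count_reads_in_region(reads: Iterable[AlignedRead], chrom: str,
                          start: int, end: int, strand: str | None = None,
                          rule: str = "any") -> int:
    """Reads whose aligned span overlaps [start, end) by >= 1 nt (``any``) or
    lies fully inside it (``contained``)."""
    if start >= end:
        raise ValueError(f"inverted interval [{start}, {end})")
    if rule not in ("any", "contained"):
        raise ValueError(f"unknown overlap rule {rule!r}")
    n = 0
    for r in reads:
        if r.chrom != chrom:
            continue
        if strand is not None and r.strand != strand:
            continue
        if rule == "any":
            if r.start < end and start < r.end:
                n += 1
        elif start <= r.start and r.end <= end:
            n += 1
    return n


def count_lost_mirna_sites(region: tuple[str, int, int],
                           binding_sites: Iterable[BedInterval],
                           strand: str | None = None) -> int:
    """Binding-site intervals overlapping the region between the proximal
    and distal sites (any overlap); strand honored when both sides carry one."""
    chrom, start, end = region
    n = 0
    for b in binding_sites:
        if b.chrom != chrom:
            continue
        if strand is not None and b.strand is not None and b.strand != strand:
            continue
        if b.start < end and start < b.end:
            n += 1
    return n


@dataclass
class ConcordanceContrast:
    top_median: float
    bottom_median: float
    p: float
    n_per_decile: int


def concordance_top_bottom(median_psi: pd.Series,
                           mrna_protein_corr: pd.Series) -> ConcordanceContrast:
    """Compare mRNA-protein correlations of the top vs bottom decile of genes
    ranked by median PSI (two-sided Wilcoxon rank-sum)."""
    shared = median_psi.index.intersection(mrna_protein_corr.index)
    if len(shared) < 20:
        raise ValueError(f"need >= 20 genes, got {len(shared)}")
    k = len(shared) // 10
    if k == 0:
        raise ValueError("decile size 0")
    ranked = median_psi[shared].sort_values()
    bottom = mrna_protein_corr[ranked.index[:k]]
    top = mrna_protein_corr[ranked.index[-k:]]
    p = float(stats.ranksums(top, bottom).pvalue)
    return ConcordanceContrast(top_median=float(top.median()),
                               bottom_median=float(bottom.median()),
                               p=p, n_per_decile=k)


def pdui_to_psi(pdui: pd.DataFrame) -> pd.DataFrame:
    """PSI = 1 - PDUI elementwise; missing preserved; values outside [0, 1]
    rejected with their coordinates."""
    vals = pdui.to_numpy(dtype=float)
    bad = (vals < 0) | (vals > 1)
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"PDUI out of [0, 1] at row {pdui.index[i]!r}, "
            f"column {pdui.columns[j]!r}: {vals[i, j]}")
    psi = 1.0 - pdui
    psi.attrs["provenance"] = "from-PDUI"
    return psi
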