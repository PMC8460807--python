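"""Usage quantification and statistics on the filtered atlas.

PSI (polyA site index) for a gene in a sample is the proximal-site read
count divided by the proximal+distal total; delta PSI is tumor minus matched
normal, so positive values mean 3'UTR shortening in tumor. Differential
usage is a per-gene paired Wilcoxon signed-rank on matched tumor/normal PSI
with Benjamini-Hochberg FDR across genes, and the PSI-expression coupling
analysis pairs gene-wise Spearman correlations with a column-permutation
empirical null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import AnnotatedSite, SitePair
from .atlas import FilterLog
from .config import QuantConfig

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Abundance filters

def apply_abundance_filters(annotated: list[AnnotatedSite],
                            metadata: pd.DataFrame,
                            config: QuantConfig | None = None,
                            log_: FilterLog | None = None
                            ) -> tuple[list[AnnotatedSite], FilterLog]:
    """Drop poorly supported sites, in order: (i) present (nonzero) in fewer
    than the required fraction of all samples; (ii) summed count below the
    group minimum in the tumor or in the normal group; (iii) pooled count
    below the minor fraction of the gene's strongest surviving site."""
    config = config or QuantConfig()
    flog = log_ if log_ is not None else FilterLog()
    samples = list(metadata.index)
    if "tissue" not in metadata.columns:
        raise ValueError("metadata needs a 'tissue' column")
    tumor = [s for s in samples if metadata.loc[s, "tissue"] == "tumor"]
    normal = [s for s in samples if metadata.loc[s, "tissue"] != "tumor"]
    if not tumor or not normal:
        raise ValueError("both tumor and non-involved samples are required")

    survivors: list[AnnotatedSite] = []
    for a in annotated:
        c = a.site.counts
        present = sum(1 for s in samples if c.get(s, 0) > 0)
        if present < config.min_presence * len(samples):
            flog.remove(a.site.chrom, a.site.strand, a.site.position, "presence")
            continue
        if (sum(c.get(s, 0) for s in tumor) < config.min_group_count or
                sum(c.get(s, 0) for s in normal) < config.min_group_count):
            flog.remove(a.site.chrom, a.site.strand, a.site.position,
                        "group-count")
            continue
        survivors.append(a)

    major: dict[str, int] = {}
    for a in survivors:
        major[a.gene_id] = max(major.get(a.gene_id, 0), a.site.pooled)
    kept: list[AnnotatedSite] = []
    for a in survivors:
        if a.site.pooled < config.min_minor_fraction * major[a.gene_id]:
            flog.remove(a.site.chrom, a.site.strand, a.site.position,
                        "minor-fraction")
        else:
            kept.append(a)
    return kept, flog


# ---------------------------------------------------------------------------
# PSI

def pair_count_matrices(pairs: list[SitePair], samples: list[str]
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    prox = pd.DataFrame(
        {s: [p.proximal.site.counts.get(s, 0) for p in pairs] for s in samples},
        index=[p.gene_id for p in pairs], dtype=float)
    dist = pd.DataFrame(
        {s: [p.distal.site.counts.get(s, 0) for p in pairs] for s in samples},
        index=[p.gene_id for p in pairs], dtype=float)
    return prox, dist


def compute_psi(proximal: pd.DataFrame, distal: pd.DataFrame) -> pd.DataFrame:
    """PSI = proximal / (proximal + distal); undefined (NaN) at zero total."""
    if (proximal.to_numpy() < 0).any() or (distal.to_numpy() < 0).any():
        raise ValueError("negative counts")
    proximal, distal = proximal.align(distal, join="inner")
    total = proximal + distal
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = proximal / total
    psi = psi.where(total > 0)
    psi.attrs["provenance"] = "from-counts"
    return psi


def matched_pairs(metadata: pd.DataFrame) -> list[tuple[str, str, str]]:
    """(subject, tumor sample, normal sample) for every complete pair."""
    out = []
    for subject, grp in metadata.groupby("subject", sort=True):
        t = grp.index[grp["tissue"] == "tumor"]
        n = grp.index[grp["tissue"] != "tumor"]
        if len(t) and len(n):
            out.append((subject, t[0], n[0]))
    return out


def compute_delta_psi(psi: pd.DataFrame, metadata: pd.DataFrame
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-subject delta PSI (tumor - normal) and its per-gene median over
    subjects with both values defined."""
    pairs = matched_pairs(metadata)
    if not pairs:
        raise ValueError("no complete tumor/normal pairs in metadata")
    deltas = pd.DataFrame(
        {subj: psi[t] - psi[n] for subj, t, n in pairs}, index=psi.index)
    return deltas, deltas.median(axis=1, skipna=True)


# ---------------------------------------------------------------------------
# Switch testing

@dataclass
class SwitchResult:
    gene_id: str
    n_pairs: int
    statistic: float
    p: float
    q: float
    median_delta_psi: float
    direction: str  # shortened / lengthened / unchanged


def test_switches(psi: pd.DataFrame, metadata: pd.DataFrame,
                  config: QuantConfig | None = None) -> pd.DataFrame:
    """Per-gene two-sided paired Wilcoxon signed-rank on matched tumor/normal
    PSI, BH-adjusted across tested genes. A gene is called shortened
    (lengthened) when q < alpha and the median delta PSI is positive
    (negative), otherwise unchanged."""
    config = config or QuantConfig()
    pairs = matched_pairs(metadata)
    rows = []
    for gene in psi.index:
        t = psi.loc[gene, [p[1] for p in pairs]].to_numpy(dtype=float)
        n = psi.loc[gene, [p[2] for p in pairs]].to_numpy(dtype=float)
        ok = ~(np.isnan(t) | np.isnan(n))
        if ok.sum() < config.min_pairs:
            continue
        diffs = t[ok] - n[ok]
        if np.all(diffs == 0):
            stat, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(t[ok], n[ok], zero_method="wilcox",
                                 alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"gene": gene, "n_pairs": int(ok.sum()),
                     "statistic": stat, "p": p,
                     "median_delta_psi": float(np.median(diffs))})
    out = pd.DataFrame(rows, columns=["gene", "n_pairs", "statistic", "p",
                                      "median_delta_psi"])
    if out.empty:
        out["q"] = out["direction"] = pd.Series(dtype=object)
        return out.set_index("gene")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    sig = out["q"] < config.fdr
    out["direction"] = np.where(
        sig & (out["median_delta_psi"] > 0), "shortened",
        np.where(sig & (out["median_delta_psi"] < 0), "lengthened",
                 "unchanged"))
    return out.set_index("gene")


# ---------------------------------------------------------------------------
# PSI-expression coupling

def correlate_psi_expression(psi: pd.DataFrame, expression: pd.DataFrame,
                             config: QuantConfig | None = None) -> pd.DataFrame:
    """Gene-wise Spearman Rho between PSI and expression across shared
    samples; constant vectors are skipped (Rho undefined)."""
    config = config or QuantConfig()
    shared = [s for s in psi.columns if s in expression.columns]
    if len(shared) < config.min_shared_samples:
        raise ValueError(
            f"only {len(shared)} shared samples "
            f"(minimum {config.min_shared_samples})")
    rows = []
    for gene in psi.index:
        if gene not in expression.index:
            continue
        x = psi.loc[gene, shared].to_numpy(dtype=float)
        y = expression.loc[gene, shared].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < config.min_shared_samples:
            continue
        if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            continue
        rho, p = stats.spearmanr(x[ok], y[ok])
        rows.append({"gene": gene, "rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows, columns=["gene", "rho", "p"])
    if out.empty:
        return out.set_index("gene")
    out["significant"] = out["p"] < 0.05
    return out.set_index("gene")


def count_beyond_threshold(corr: pd.DataFrame,
                           config: QuantConfig | None = None) -> int:
    config = config or QuantConfig()
    rho = corr["rho"]
    if config.rho_two_sided:
        return int((rho.abs() > config.rho_threshold).sum())
    return int((rho > config.rho_threshold).sum())


def permutation_empirical_p(psi: pd.DataFrame, expression: pd.DataFrame,
                            observed_count: int,
                            config: QuantConfig | None = None,
                            n_permutations: int | None = None,
                            seed: int = 0) -> float:
    """Empirical probability of seeing ``observed_count`` or more coupled
    genes by chance. Each permutation shuffles the sample labels of the PSI
    matrix (columns permuted jointly across genes, preserving gene-gene
    structure), recounts genes with Rho beyond the threshold, and the add-one
    estimate (1 + hits) / (n + 1) is returned."""
    config = config or QuantConfig()
    n_perm = n_permutations if n_permutations is not None else config.n_permutations
    if n_perm < 1:
        raise ValueError("n_permutations must be >= 1")
    if observed_count < 0:
        raise ValueError("observed_count must be >= 0")
    rng = np.random.default_rng(seed)

    shared = [s for s in psi.columns if s in expression.columns]
    genes = [g for g in psi.index if g in expression.index]
    X = psi.loc[genes, shared].to_numpy(dtype=float)
    Y = expression.loc[genes, shared].to_numpy(dtype=float)
    complete = ~(np.isnan(X).any(axis=1) | np.isnan(Y).any(axis=1))
    if not complete.all():
        log.info("permutation null drops %d genes with missing values",
                 int((~complete).sum()))
    X, Y = X[complete], Y[complete]
    keep = (np.ptp(X, axis=1) > 0) & (np.ptp(Y, axis=1) > 0)
    X, Y = X[keep], Y[keep]
    if X.shape[0] == 0:
        return 1.0

    rx = _rank_rows(X)
    ry = _rank_rows(Y)
    hits = 0
    n = rx.shape[1]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rho = np.einsum("ij,ij->i", rx[:, perm], ry)
        if config.rho_two_sided:
            stat = int((np.abs(rho) > config.rho_threshold).sum())
        else:
            stat = int((rho > config.rho_threshold).sum())
        if stat >= observed_count:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def _rank_rows(M: np.ndarray) -> np.ndarray:
    r = stats.rankdata(M, axis=1).astype(float)
    r -= r.mean(axis=1, keepdims=True)
    norm = np.sqrt((r ** 2).sum(axis=1, keepdims=True))
    return r / np.where(norm == 0, 1.0, norm)
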