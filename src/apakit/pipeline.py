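"""End-to-end orchestration and the summary reporter.

Stages run in order atlas -> annotate -> quantify -> statistics -> indices ->
survival -> summary; every run directory receives the effective config echo,
per-stage counters, and TSV/JSON outputs sufficient to reproduce the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from . import annotation, atlas as atlas_mod, indices, quantify, survival
from .config import PipelineConfig
from .formats import Genome, read_cleavage_alignments, read_gene_models, \
    write_matrix

log = logging.getLogger(__name__)

STAGES = ("atlas", "annotate", "quantify", "statistics", "indices",
          "survival", "summary")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunPaths:
    genome: str | Path
    annotation: str | Path
    alignments: str | Path
    metadata: str | Path
    expression: str | Path | None = None
    clinical: str | Path | None = None
    mirna_bed: str | Path | None = None
    machinery_genes: str | Path | None = None

    def validate(self) -> None:
        for name in ("genome", "annotation", "alignments", "metadata"):
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"required input {name!r}: {p}")
        for name in ("expression", "clinical", "mirna_bed", "machinery_genes"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"optional input {name!r}: {p}")


def run_pipeline(paths: RunPaths, outdir: str | Path,
                 config: PipelineConfig | None = None,
                 stop_after: str = "summary") -> dict:
    """Execute the pipeline, writing all stage outputs under ``outdir``."""
    config = config or PipelineConfig()
    paths.validate()
    if stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.echo(outdir / "config.yaml")
    results: dict = {"counters": {}}

    def _stage(name):
        return STAGES.index(name) <= STAGES.index(stop_after)

    try:
        genome = Genome(paths.genome)
        stream = read_cleavage_alignments(paths.alignments)
        if stream.tabular:
            events = atlas_mod.events_from_table(stream.events())
        else:
            events = atlas_mod.extract_cleavage_loci(
                stream.reads(), config.atlas.protocol)
        sites, flog = atlas_mod.build_atlas(events, genome, config.atlas)
        results["sites"] = sites
        results["atlas_log"] = flog
        results["counters"]["atlas"] = dict(flog.counters)
        _write_atlas(sites, outdir)
    except Exception as exc:  # noqa: BLE001 - halt with the stage named
        raise StageError("atlas", exc) from exc
    if not _stage("annotate"):
        return results

    try:
        genes = read_gene_models(paths.annotation)
        chrom_lengths = {c: genome.length(c) for c in genome.chroms}
        annotation.extend_gene_regions(genes, chrom_lengths, config.annotation)
        annotated, unassigned = annotation.assign_sites_to_genes(sites, genes)
        metadata = pd.read_csv(paths.metadata, sep="\t", index_col=0)
        retained, qlog = quantify.apply_abundance_filters(
            annotated, metadata, config.quant)
        pairs = annotation.make_pairs(retained, genes)
        results.update(genes=genes, annotated=annotated, retained=retained,
                       pairs=pairs, metadata=metadata)
        results["counters"]["annotate"] = {
            "assigned": len(annotated), "unassigned": len(unassigned),
            "retained": len(retained), "pairs": len(pairs),
            **dict(qlog.counters)}
        _write_annotated(retained, pairs, outdir)
    except Exception as exc:
        raise StageError("annotate", exc) from exc
    if not _stage("quantify"):
        return results

    try:
        samples = list(metadata.index)
        prox, dist = quantify.pair_count_matrices(pairs, samples)
        psi = quantify.compute_psi(prox, dist)
        deltas, median_delta = quantify.compute_delta_psi(psi, metadata)
        results.update(psi=psi, delta_psi=deltas, median_delta=median_delta)
        write_matrix(psi, outdir / "psi.tsv")
        write_matrix(deltas, outdir / "delta_psi.tsv")
    except Exception as exc:
        raise StageError("quantify", exc) from exc
    if not _stage("statistics"):
        return results

    try:
        switches = quantify.test_switches(psi, metadata, config.quant)
        switches.to_csv(outdir / "switches.tsv", sep="\t")
        results["switches"] = switches
        if paths.expression is not None:
            expression = pd.read_csv(paths.expression, sep="\t", index_col=0)
            corr = quantify.correlate_psi_expression(psi, expression,
                                                     config.quant)
            observed = quantify.count_beyond_threshold(corr, config.quant)
            emp_p = quantify.permutation_empirical_p(
                psi, expression, observed, config.quant, seed=config.seed)
            corr.to_csv(outdir / "correlations.tsv", sep="\t")
            results.update(correlations=corr, observed_coupled=observed,
                           empirical_p=emp_p, expression=expression)
            (outdir / "coupling.json").write_text(json.dumps(
                {"observed_coupled": observed, "empirical_p": emp_p}))
    except Exception as exc:
        raise StageError("statistics", exc) from exc
    if not _stage("indices"):
        return results

    try:
        load = indices.psi_load(psi)
        load.to_csv(outdir / "psi_load.tsv", sep="\t")
        results["psi_load"] = load
        if paths.expression is not None and paths.machinery_genes is not None:
            gene_set = [g.strip() for g in
                        Path(paths.machinery_genes).read_text().split()
                        if g.strip()]
            pa = indices.pa_machinery_index(results["expression"], gene_set)
            pa.to_csv(outdir / "pa_machinery_index.tsv", sep="\t")
            results["pa_machinery_index"] = pa
    except Exception as exc:
        raise StageError("indices", exc) from exc
    if not _stage("survival"):
        return results

    try:
        if paths.clinical is not None:
            clinical = pd.read_csv(paths.clinical, sep="\t", index_col=0)
            selected = survival.select_features_lasso(
                psi, clinical, config=config.survival, seed=config.seed)
            if selected:
                model = survival.fit_pi_model(psi, clinical,
                                              selected=selected)
                pi = survival.loocv_prognostic_index(psi, clinical, selected)
                report = survival.stratify_and_logrank(
                    pi, clinical, orientation=config.survival.risk_orientation)
                (outdir / "model.json").write_text(json.dumps({
                    "genes": model.genes,
                    "beta": model.beta.to_dict(),
                    "covariates": model.covariate_coef.to_dict()}, indent=1))
                pi.to_csv(outdir / "pi.tsv", sep="\t")
                report.groups.to_csv(outdir / "risk_groups.tsv", sep="\t")
                (outdir / "logrank.json").write_text(json.dumps({
                    "chi2": report.chi2, "p": report.p,
                    "hazard_ratio": report.hazard_ratio}))
                results.update(model=model, pi=pi, logrank=report,
                               selected=selected)
            else:
                log.warning("lasso selected no genes; survival stage skipped")
                results["selected"] = []
    except Exception as exc:
        raise StageError("survival", exc) from exc
    if not _stage("summary"):
        return results

    try:
        summary = summarize_run(results)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
        results["summary"] = summary
    except Exception as exc:
        raise StageError("summary", exc) from exc
    return results


def _write_atlas(sites, outdir: Path) -> None:
    with open(outdir / "atlas.bed", "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.position}\t{s.position + 1}\t"
                     f"{s.site_id}\t{s.pooled}\t{s.strand}\n")
    rows = [{"site_id": s.site_id, "chrom": s.chrom, "strand": s.strand,
             "position": s.position, "pooled": s.pooled,
             "hexamer": s.hexamer or "", "hexamer_offset": s.hexamer_offset,
             "members": ",".join(map(str, s.members))} for s in sites]
    pd.DataFrame(rows).to_csv(outdir / "atlas.tsv", sep="\t", index=False)


def _write_annotated(retained, pairs, outdir: Path) -> None:
    rows = [{"site_id": a.site.site_id, "gene": a.gene_id,
             "position": a.site.position, "strand": a.site.strand,
             "location": a.location, "rank": a.rank} for a in retained]
    pd.DataFrame(rows).to_csv(outdir / "sites_annotated.tsv", sep="\t",
                              index=False)
    rows = [{"gene": p.gene_id, "proximal": p.proximal.site.position,
             "distal": p.distal.site.position, "pair_type": p.pair_type,
             "proximal_location": p.proximal.location,
             "distal_location": p.distal.location,
             "flagged": p.flagged} for p in pairs]
    pd.DataFrame(rows).to_csv(outdir / "pairs.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Summary reporter

def percent(numerator: float, denominator: float) -> int | None:
    """100 * numerator / denominator rounded half-up to an integer percent;
    None (undefined, not 0) when the denominator is zero."""
    if denominator == 0:
        return None
    frac = Decimal(numerator) * 100 / Decimal(denominator)
    return int(frac.quantize(Decimal(1), rounding=ROUND_HALF_UP))


def summarize_counts(n_genes: int, n_multi_site_genes: int,
                     n_shortened: int, n_lengthened: int,
                     n_sites: int | None = None,
                     pair_type_counts: dict[str, int] | None = None) -> dict:
    """Bookkeeping arithmetic over atlas/switch counts: totals as sums of
    their partitions, fractions as half-up-rounded integer percentages."""
    n_switched = n_shortened + n_lengthened
    out = {
        "n_sites": n_sites,
        "n_genes": n_genes,
        "n_multi_site_genes": n_multi_site_genes,
        "multi_site_percent": percent(n_multi_site_genes, n_genes),
        "n_switched": n_switched,
        "switched_percent_of_multi": percent(n_switched, n_multi_site_genes),
        "n_shortened": n_shortened,
        "n_lengthened": n_lengthened,
        "shortened_percent_of_switched": percent(n_shortened, n_switched),
    }
    if pair_type_counts:
        out["pair_type_counts"] = dict(pair_type_counts)
        out["pair_type_total"] = sum(pair_type_counts.values())
    return out


def summarize_run(results: dict) -> dict:
    """Recompute the bookkeeping summary from an in-memory pipeline run."""
    annotated = results.get("retained", [])
    pairs = results.get("pairs", [])
    genes_with_sites = {a.gene_id for a in annotated}
    per_gene: dict[str, int] = {}
    for a in annotated:
        per_gene[a.gene_id] = per_gene.get(a.gene_id, 0) + 1
    multi = [g for g, n in per_gene.items() if n > 1]

    switches = results.get("switches")
    n_short = n_long = 0
    direction = {}
    if switches is not None and not switches.empty:
        direction = switches["direction"].to_dict()
        n_short = int((switches["direction"] == "shortened").sum())
        n_long = int((switches["direction"] == "lengthened").sum())

    pair_types: dict[str, int] = {}
    switch_by_pair_type: dict[str, dict[str, int]] = {}
    location_prox: dict[str, int] = {}
    location_dist: dict[str, int] = {}
    for p in pairs:
        pair_types[p.pair_type] = pair_types.get(p.pair_type, 0) + 1
        # downstream-extension sites report with the 3'UTR bucket
        lp = "3UTR" if p.proximal.location == "downstream-extension" \
            else p.proximal.location
        ld = "3UTR" if p.distal.location == "downstream-extension" \
            else p.distal.location
        location_prox[lp] = location_prox.get(lp, 0) + 1
        location_dist[ld] = location_dist.get(ld, 0) + 1
        d = direction.get(p.gene_id, "unchanged")
        if d != "unchanged":
            by = switch_by_pair_type.setdefault(d, {})
            by[p.pair_type] = by.get(p.pair_type, 0) + 1

    out = summarize_counts(
        n_genes=len(genes_with_sites), n_multi_site_genes=len(multi),
        n_shortened=n_short, n_lengthened=n_long,
        n_sites=len(annotated), pair_type_counts=pair_types)
    out["proximal_location_counts"] = location_prox
    out["distal_location_counts"] = location_dist
    out["proximal_location_percent"] = {
        k: percent(v, len(pairs)) for k, v in location_prox.items()}
    out["distal_location_percent"] = {
        k: percent(v, len(pairs)) for k, v in location_dist.items()}
    out["switches_by_pair_type"] = switch_by_pair_type
    return out
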