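"""Assign atlas sites to genes and classify their genomic context.

Because 3'UTR isoforms are incompletely annotated, every gene is extended
downstream of its annotated 3' end (5 kb, or half the intergenic gap when the
next gene is closer than 10 kb) before sites are assigned. A site falling in
that extension is treated as part of the terminal exon for pair typing and is
pooled with the 3'UTR bucket in summaries.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from intervaltree import IntervalTree

from .atlas import PolyASite
from .config import AnnotationConfig
from .formats import GeneModel, Interval

LOCATION_CLASSES = ("3UTR", "exon", "intron", "downstream-extension")
PAIR_TYPES = ("same-exon", "composite-exon", "skipped-exon")


@dataclass
class AnnotatedSite:
    site: PolyASite
    gene_id: str
    location: str        # one of LOCATION_CLASSES
    rank: int = 0        # 1 = 5'-most retained site of the gene


@dataclass
class SitePair:
    gene_id: str
    proximal: AnnotatedSite
    distal: AnnotatedSite
    pair_type: str
    flagged: bool = False  # no classification rule matched; forced composite


# ---------------------------------------------------------------------------
# Downstream extension

def extend_gene_regions(genes: dict[str, GeneModel],
                        chrom_lengths: dict[str, int],
                        config: AnnotationConfig | None = None
                        ) -> dict[str, GeneModel]:
    """Fill ``extended_end`` on every gene (mutates and returns ``genes``)."""
    config = config or AnnotationConfig()
    by_chrom: dict[str, list[GeneModel]] = defaultdict(list)
    for gm in genes.values():
        by_chrom[gm.chrom].append(gm)

    for gm in genes.values():
        neighbors = by_chrom[gm.chrom]
        if config.same_strand_neighbors:
            neighbors = [g for g in neighbors if g.strand == gm.strand]
        if gm.strand == "+":
            end3 = gm.end
            starts = [g.start for g in neighbors
                      if g.gene_id != gm.gene_id and g.start >= end3]
            gap = min(starts) - end3 if starts else None
        else:
            end3 = gm.start
            ends = [g.end for g in neighbors
                    if g.gene_id != gm.gene_id and g.end <= end3]
            gap = end3 - max(ends) if ends else None

        if gap is None or gap >= config.min_gap_for_full:
            ext = config.extension_bp
        else:
            ext = gap // 2
        ext = min(ext, config.extension_bp)
        if gm.strand == "+":
            gm.extended_end = min(end3 + ext, chrom_lengths[gm.chrom])
        else:
            gm.extended_end = max(end3 - ext, 0)
    return genes


def _assignable_span(gm: GeneModel) -> Interval:
    """Genomic interval [start, extended_end) in transcript orientation."""
    if gm.extended_end is None:
        raise ValueError(f"gene {gm.gene_id} has no extension; "
                         "run extend_gene_regions first")
    if gm.strand == "+":
        return (gm.start, gm.extended_end)
    return (gm.extended_end, gm.end)


# ---------------------------------------------------------------------------
# Site -> gene assignment

def assign_sites_to_genes(sites: list[PolyASite], genes: dict[str, GeneModel]
                          ) -> tuple[list[AnnotatedSite], list[PolyASite]]:
    """Assign each site to the strand-matching gene whose (extended) span
    contains it; ambiguity resolved by nearest annotated 3' end, then by
    smaller gene id. Returns (annotated sites, unassigned sites)."""
    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for gm in genes.values():
        s, e = _assignable_span(gm)
        if s < e:
            trees[(gm.chrom, gm.strand)][s:e] = gm

    annotated: list[AnnotatedSite] = []
    unassigned: list[PolyASite] = []
    for site in sites:
        hits = trees.get((site.chrom, site.strand), IntervalTree())[site.position]
        if not hits:
            unassigned.append(site)
            continue
        def _key(iv):
            gm = iv.data
            dist = abs(site.position - (gm.end - 1 if gm.strand == "+" else gm.start))
            return (dist, gm.gene_id)
        gm = min(hits, key=_key).data
        annotated.append(AnnotatedSite(
            site=site, gene_id=gm.gene_id,
            location=classify_site_location(site.position, gm)))

    _assign_ranks(annotated, genes)
    return annotated, unassigned


def _assign_ranks(annotated: list[AnnotatedSite],
                  genes: dict[str, GeneModel]) -> None:
    per_gene: dict[str, list[AnnotatedSite]] = defaultdict(list)
    for a in annotated:
        per_gene[a.gene_id].append(a)
    for gid, sites in per_gene.items():
        reverse = genes[gid].strand == "-"
        sites.sort(key=lambda a: a.site.position, reverse=reverse)
        for rank, a in enumerate(sites, 1):
            a.rank = rank


# ---------------------------------------------------------------------------
# Location classification

def classify_site_location(pos: int, gm: GeneModel) -> str:
    """3UTR > exon > intron > downstream-extension, first match wins."""
    if any(s <= pos < e for s, e in gm.utr3):
        return "3UTR"
    for exons in gm.transcripts.values():
        if any(s <= pos < e for s, e in exons):
            return "exon"
    if gm.contains(pos):
        return "intron"
    span = _assignable_span(gm)
    if span[0] <= pos < span[1]:
        return "downstream-extension"
    raise ValueError(
        f"position {pos} outside gene {gm.gene_id} and its extension")


# ---------------------------------------------------------------------------
# Pair typing

def _effective_exons(gm: GeneModel, tid: str) -> list[Interval]:
    """Exons of one transcript; when the transcript reaches the gene's
    annotated 3' end, its terminal exon is stretched to the extended end so
    extension sites behave as terminal-exon sites. Shorter isoforms are not
    stretched — their annotated 3' boundary is real isoform structure."""
    exons = list(gm.transcripts[tid])
    if gm.extended_end is None:
        return exons
    s, e = exons[-1]
    if gm.strand == "+":
        if e == gm.end:
            exons[-1] = (s, max(e, gm.extended_end))
    else:
        if s == gm.start:
            exons[-1] = (min(s, gm.extended_end), e)
    return exons


def _containing_exons(gm: GeneModel, pos: int) -> list[tuple[str, Interval]]:
    out = []
    for tid in gm.transcripts:
        for iv in _effective_exons(gm, tid):
            if iv[0] <= pos < iv[1]:
                out.append((tid, iv))
    return out


def _is_5prime_of(gm: GeneModel, a: int, b: int) -> bool:
    return a < b if gm.strand == "+" else a > b


def classify_pair_type(gm: GeneModel, proximal_pos: int, distal_pos: int
                       ) -> tuple[str, bool]:
    """Type a proximal/distal site pair from the annotated isoforms.

    same-exon: one exon of one transcript holds both sites. skipped-exon:
    the proximal site's exon is fully intronic in (absent from) a transcript
    holding the distal site. composite-exon: the proximal site's exon runs
    past a 5' splice donor used by a distal-holding transcript (intron
    retention past that donor). Precedence same > skipped > composite; a pair
    matching no rule is labelled composite and flagged.
    """
    if not _is_5prime_of(gm, proximal_pos, distal_pos):
        raise ValueError("proximal site must lie 5' of the distal site")

    prox_exons = _containing_exons(gm, proximal_pos)
    dist_exons = _containing_exons(gm, distal_pos)
    distal_tids = {tid for tid, _ in dist_exons}

    for tid, iv in prox_exons:
        if tid in distal_tids and iv[0] <= distal_pos < iv[1]:
            return "same-exon", False

    # skipped-exon: proximal exon absent (fully intronic) in a distal isoform
    for _, pe in prox_exons:
        for tid2 in distal_tids:
            exons2 = _effective_exons(gm, tid2)
            span2 = (min(s for s, _ in exons2), max(e for _, e in exons2))
            inside = span2[0] <= pe[0] and pe[1] <= span2[1]
            overlaps = any(s < pe[1] and pe[0] < e for s, e in exons2)
            if inside and not overlaps:
                return "skipped-exon", False

    # composite-exon: proximal exon extends past a donor used by a distal isoform
    for _, pe in prox_exons:
        for tid2 in distal_tids:
            exons2 = _effective_exons(gm, tid2)
            for x in exons2[:-1]:          # non-terminal exons carry a donor
                # donor = the exon's 3' boundary (half-open cut point) in
                # transcript orientation; the proximal exon extends past it
                # when that cut point falls strictly inside the exon
                donor = x[1] if gm.strand == "+" else x[0]
                if _overlap(pe, x) and pe[0] < donor < pe[1]:
                    return "composite-exon", False

    return "composite-exon", True


def _overlap(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def make_pairs(annotated: list[AnnotatedSite], genes: dict[str, GeneModel]
               ) -> list[SitePair]:
    """One proximal/distal pair per multi-site gene: the 5'-most and 3'-most
    retained sites in transcript orientation."""
    per_gene: dict[str, list[AnnotatedSite]] = defaultdict(list)
    for a in annotated:
        per_gene[a.gene_id].append(a)
    pairs: list[SitePair] = []
    for gid in sorted(per_gene):
        reverse = genes[gid].strand == "-"
        sites = sorted(per_gene[gid], key=lambda a: a.site.position,
                       reverse=reverse)
        if len(sites) < 2:
            continue
        proximal, distal = sites[0], sites[-1]
        ptype, flagged = classify_pair_type(
            genes[gid], proximal.site.position, distal.site.position)
        pairs.append(SitePair(gid, proximal, distal, ptype, flagged))
    return pairs
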