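"""PolyA-site atlas construction from 3'-end cleavage events.

The pipeline is: extract a cleavage locus per aligned read (the terminal
aligned base on the polyA side, soft clips excluded), drop loci that look like
oligo-dT internal priming (A-rich genomic context around the locus), pool
events across samples and cluster nearby cleavage positions onto dominant
loci, require a polyadenylation-signal hexamer upstream of each cluster
representative, and finally enforce a minimum spacing between accepted sites
so each retained site carries its own signal and cis-regulatory context.

Offsets are transcript-relative: offset 0 is the cleavage base, negative
offsets are upstream (5') of it, and sequence is read on the transcript
strand.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .config import AtlasConfig
from .formats import AlignedRead, CleavageEvent, Genome

Locus = tuple[str, str, int]  # chrom, transcript strand, position


@dataclass
class Cluster:
    chrom: str
    strand: str
    position: int                      # representative = seed position
    members: list[int]
    counts: dict[str, int]             # per-sample summed over members

    @property
    def pooled(self) -> int:
        return sum(self.counts.values())


@dataclass
class PolyASite:
    """A filtered, clustered cleavage site retained in the atlas."""

    site_id: str
    chrom: str
    strand: str
    position: int
    counts: dict[str, int]
    hexamer: str | None = None
    hexamer_offset: int | None = None  # start offset in [-30, -10]
    members: list[int] = field(default_factory=list)

    @property
    def pooled(self) -> int:
        return sum(self.counts.values())


@dataclass
class FilterLog:
    """Per-stage counters plus the removed loci with their reason."""

    counters: Counter = field(default_factory=Counter)
    removed: list[tuple[str, str, int, str]] = field(default_factory=list)

    def remove(self, chrom: str, strand: str, pos: int, reason: str) -> None:
        self.counters[reason] += 1
        self.removed.append((chrom, strand, pos, reason))

    def reasons_at(self, chrom: str, strand: str, pos: int) -> set[str]:
        return {r for c, s, p, r in self.removed
                if (c, s, p) == (chrom, strand, pos)}


def _5p_key(strand: str, pos: int) -> int:
    """Sort key putting the 5'-most position (transcript orientation) first."""
    return pos if strand == "+" else -pos


# ---------------------------------------------------------------------------
# Cleavage extraction

def extract_cleavage_loci(reads: Iterable[AlignedRead],
                          protocol: str = "rev") -> dict[Locus, dict[str, int]]:
    """Reduce aligned reads to per-sample cleavage-event counts.

    ``rev`` protocol (3'-end-enriched libraries read antisense to the mRNA):
    the cleavage locus is the terminal aligned base at the read's 5' end and
    the transcript strand is opposite the alignment strand. ``fwd``: locus at
    the read's 3' end, transcript strand equals the alignment strand.
    """
    if protocol not in ("rev", "fwd"):
        raise ValueError(f"unknown protocol {protocol!r}")
    events: dict[Locus, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for r in reads:
        if protocol == "rev":
            tstrand = "-" if r.strand == "+" else "+"
            locus = r.end - 1 if r.strand == "-" else r.start
        else:
            tstrand = r.strand
            locus = r.end - 1 if r.strand == "+" else r.start
        events[(r.chrom, tstrand, locus)][r.sample] += 1
    return {k: dict(v) for k, v in events.items()}


def events_from_table(rows: Iterable[CleavageEvent]) -> dict[Locus, dict[str, int]]:
    events: dict[Locus, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for ev in rows:
        if ev.count < 1:
            continue
        events[(ev.chrom, ev.strand, ev.position)][ev.sample] += ev.count
    return {k: dict(v) for k, v in events.items()}


# ---------------------------------------------------------------------------
# Internal-priming filter

def _upstream_window(genome: Genome, chrom: str, pos: int, strand: str,
                     up: int, down: int) -> tuple[str, int]:
    """Transcript-orientation window around ``pos``; returns (sequence,
    actual upstream extent) so offset o maps to index o + up_actual."""
    if strand == "+":
        up_avail = min(up, pos)
        down_avail = min(down, genome.length(chrom) - 1 - pos)
    else:
        up_avail = min(up, genome.length(chrom) - 1 - pos)
        down_avail = min(down, pos)
    return genome.transcript_window(chrom, pos, strand, up_avail, down_avail), up_avail


def is_internal_priming(genome: Genome, chrom: str, strand: str, pos: int,
                        config: AtlasConfig) -> bool:
    """A-rich context test in the [-10, +10] window around the cleavage base:
    flagged when the window holds a run of more than ``max_a_run`` consecutive
    As or more than ``max_sparse_a`` As inside any 10-nt subwindow."""
    lo, hi = config.priming_window
    seq, _ = _upstream_window(genome, chrom, pos, strand, -lo, hi)
    if not seq:
        return False
    run = best = 0
    for base in seq:
        run = run + 1 if base == "A" else 0
        best = max(best, run)
    if best > config.max_a_run:
        return True
    if len(seq) >= 10:
        a_flags = [1 if b == "A" else 0 for b in seq]
        window = sum(a_flags[:10])
        if window > config.max_sparse_a:
            return True
        for i in range(10, len(seq)):
            window += a_flags[i] - a_flags[i - 10]
            if window > config.max_sparse_a:
                return True
    return False


def filter_internal_priming(events: dict[Locus, dict[str, int]], genome: Genome,
                            config: AtlasConfig,
                            log: FilterLog | None = None
                            ) -> dict[Locus, dict[str, int]]:
    log = log if log is not None else FilterLog()
    kept: dict[Locus, dict[str, int]] = {}
    for (chrom, strand, pos), counts in events.items():
        if is_internal_priming(genome, chrom, strand, pos, config):
            log.remove(chrom, strand, pos, "internal-priming")
        else:
            kept[(chrom, strand, pos)] = counts
    return kept


# ---------------------------------------------------------------------------
# Hexamer requirement

def find_hexamer(genome: Genome, chrom: str, strand: str, pos: int,
                 config: AtlasConfig) -> tuple[str, int] | None:
    """Best polyadenylation signal whose start offset lies in the configured
    upstream window. Priority: catalogue order first, then the occurrence
    closest to the cleavage site."""
    lo, hi = config.hexamer_window   # e.g. (-30, -10), start offsets inclusive
    for h in config.hexamers:
        if len(h) != 6:
            raise ValueError(f"hexamer {h!r} is not 6 nt")
    up_needed = -lo
    down_needed = max(0, hi + 6 - 1)
    seq, up_actual = _upstream_window(genome, chrom, pos, strand,
                                      up_needed, down_needed)
    for hexamer in config.hexamers:
        best: int | None = None
        start = seq.find(hexamer)
        while start != -1:
            offset = start - up_actual
            if lo <= offset <= hi:
                best = offset if best is None else max(best, offset)
            start = seq.find(hexamer, start + 1)
        if best is not None:
            return hexamer, best
    return None


def require_hexamer(clusters: list[Cluster], genome: Genome, config: AtlasConfig,
                    log: FilterLog | None = None
                    ) -> list[tuple[Cluster, str, int]]:
    """Keep clusters whose representative has an upstream signal; annotate it."""
    log = log if log is not None else FilterLog()
    out: list[tuple[Cluster, str, int]] = []
    for cl in clusters:
        hit = find_hexamer(genome, cl.chrom, cl.strand, cl.position, config)
        if hit is None:
            log.remove(cl.chrom, cl.strand, cl.position, "no-hexamer")
        else:
            out.append((cl, hit[0], hit[1]))
    return out


# ---------------------------------------------------------------------------
# Clustering and spacing

def cluster_events(events: dict[Locus, dict[str, int]],
                   radius: int = 5) -> list[Cluster]:
    """Greedy one-pass clustering per (chrom, transcript strand): repeatedly
    seed on the unassigned position with the highest pooled count (ties to the
    5'-most) and absorb unassigned positions within ``radius`` nt."""
    by_cs: dict[tuple[str, str], dict[int, dict[str, int]]] = defaultdict(dict)
    for (chrom, strand, pos), counts in events.items():
        by_cs[(chrom, strand)][pos] = counts

    clusters: list[Cluster] = []
    for (chrom, strand), posmap in sorted(by_cs.items()):
        positions = sorted(posmap)
        pooled = {p: sum(posmap[p].values()) for p in positions}
        order = sorted(positions,
                       key=lambda p: (-pooled[p], _5p_key(strand, p)))
        assigned: set[int] = set()
        for seed in order:
            if seed in assigned:
                continue
            left = bisect_left(positions, seed - radius)
            right = bisect_right(positions, seed + radius)
            members = [p for p in positions[left:right] if p not in assigned]
            assigned.update(members)
            counts: dict[str, int] = defaultdict(int)
            for p in members:
                for sample, c in posmap[p].items():
                    counts[sample] += c
            clusters.append(Cluster(chrom, strand, seed, sorted(members),
                                    dict(counts)))
    return clusters


def select_dominant_sites(clusters: list[Cluster], min_spacing: int = 125,
                          log: FilterLog | None = None) -> list[Cluster]:
    """Greedy spacing filter: walk clusters in descending pooled count (ties
    to the 5'-most) and accept one only if its representative is at least
    ``min_spacing`` nt from every already-accepted representative on the same
    chromosome and transcript strand."""
    if min_spacing < 1:
        raise ValueError("min_spacing must be >= 1")
    log = log if log is not None else FilterLog()
    accepted: list[Cluster] = []
    taken: dict[tuple[str, str], list[int]] = defaultdict(list)
    order = sorted(clusters,
                   key=lambda c: (-c.pooled, c.chrom, c.strand,
                                  _5p_key(c.strand, c.position)))
    for cl in order:
        near = taken[(cl.chrom, cl.strand)]
        if any(abs(cl.position - p) < min_spacing for p in near):
            log.remove(cl.chrom, cl.strand, cl.position, "spacing")
            continue
        near.append(cl.position)
        accepted.append(cl)
    accepted.sort(key=lambda c: (c.chrom, c.strand, c.position))
    return accepted


# ---------------------------------------------------------------------------
# End-to-end atlas

def build_atlas(events: dict[Locus, dict[str, int]], genome: Genome,
                config: AtlasConfig | None = None
                ) -> tuple[list[PolyASite], FilterLog]:
    """Run internal-priming filtering, clustering, the hexamer requirement
    (at the stage set by ``config.hexamer_stage``) and dominant-site spacing;
    returns atlas sites plus the removal log."""
    config = config or AtlasConfig()
    config.validate()
    log = FilterLog()
    log.counters["events-in"] = len(events)

    kept = filter_internal_priming(events, genome, config, log)

    if config.hexamer_stage == "event":
        filtered: dict[Locus, dict[str, int]] = {}
        for (chrom, strand, pos), counts in kept.items():
            if find_hexamer(genome, chrom, strand, pos, config) is None:
                log.remove(chrom, strand, pos, "no-hexamer")
            else:
                filtered[(chrom, strand, pos)] = counts
        kept = filtered

    clusters = cluster_events(kept, config.cluster_radius)
    log.counters["clusters"] = len(clusters)

    if config.hexamer_stage == "cluster":
        annotated = require_hexamer(clusters, genome, config, log)
    else:
        annotated = [(cl, None, None) for cl in clusters]

    hex_by_locus = {(cl.chrom, cl.strand, cl.position): (h, o)
                    for cl, h, o in annotated}
    selected = select_dominant_sites([cl for cl, _, _ in annotated],
                                     config.min_spacing, log)

    sites: list[PolyASite] = []
    for i, cl in enumerate(selected):
        h, o = hex_by_locus[(cl.chrom, cl.strand, cl.position)]
        sites.append(PolyASite(
            site_id=f"PAS{i + 1:06d}", chrom=cl.chrom, strand=cl.strand,
            position=cl.position, counts=cl.counts, hexamer=h,
            hexamer_offset=o, members=cl.members))
    log.counters["sites-retained"] = len(sites)
    return sites, log
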