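"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

import numpy as np


def bh_stepup(pvalues):
    """Benjamini-Hochberg adjusted p-values by the literal step-up rule."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def greedy_cluster(pos_counts: dict[int, int], radius: int, strand: str):
    """Literal simulation of dominant-locus clustering on one strand:
    repeatedly take the unassigned position with the highest count (ties to
    the 5'-most) and absorb unassigned positions within the radius."""
    remaining = dict(pos_counts)
    clusters = []
    while remaining:
        best = None
        for pos, cnt in remaining.items():
            key = (-cnt, pos if strand == "+" else -pos)
            if best is None or key < best[0]:
                best = (key, pos)
        seed = best[1]
        members = [p for p in remaining if abs(p - seed) <= radius]
        total = sum(remaining[p] for p in members)
        clusters.append((seed, sorted(members), total))
        for p in members:
            del remaining[p]
    return clusters


def greedy_spacing(rep_counts: dict[int, int], min_spacing: int, strand: str):
    """Literal simulation of the ranked spacing rule."""
    order = sorted(rep_counts,
                   key=lambda p: (-rep_counts[p], p if strand == "+" else -p))
    accepted = []
    for pos in order:
        if all(abs(pos - q) >= min_spacing for q in accepted):
            accepted.append(pos)
    return sorted(accepted)


def logrank_chi2(times_a, events_a, times_b, events_b):
    """Two-group log-rank chi-square from first principles."""
    records = [(t, e, 0) for t, e in zip(times_a, events_a)]
    records += [(t, e, 1) for t, e in zip(times_b, events_b)]
    event_times = sorted({t for t, e, _ in records if e == 1})
    observed_a = expected_a = variance = 0.0
    for t in event_times:
        at_risk = [(g) for tt, e, g in records if tt >= t]
        n = len(at_risk)
        n_a = sum(1 for g in at_risk if g == 0)
        d = sum(1 for tt, e, _ in records if tt == t and e == 1)
        d_a = sum(1 for tt, e, g in records if tt == t and e == 1 and g == 0)
        observed_a += d_a
        expected_a += d * n_a / n
        if n > 1:
            variance += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if variance == 0:
        return 0.0
    return (observed_a - expected_a) ** 2 / variance


# ---------------------------------------------------------------------------
# Gene-structure classification oracle (naive interval logic)

def oracle_location(pos, gm):
    for s, e in gm.utr3:
        if s <= pos < e:
            return "3UTR"
    for exons in gm.transcripts.values():
        for s, e in exons:
            if s <= pos < e:
                return "exon"
    if gm.start <= pos < gm.end:
        return "intron"
    return "downstream-extension"


def _oracle_exons(gm, tid):
    exons = [list(iv) for iv in gm.transcripts[tid]]
    last = exons[-1]
    if gm.strand == "+" and last[1] == gm.end:
        last[1] = max(last[1], gm.extended_end)
    if gm.strand == "-" and last[0] == gm.start:
        last[0] = min(last[0], gm.extended_end)
    return [tuple(iv) for iv in exons]


def oracle_pair_type(gm, prox, dist):
    """Naive re-derivation of same/skipped/composite precedence."""
    tx_exons = {tid: _oracle_exons(gm, tid) for tid in gm.transcripts}

    def holding(pos):
        return [(tid, iv) for tid, ivs in tx_exons.items()
                for iv in ivs if iv[0] <= pos < iv[1]]

    dist_tids = {tid for tid, _ in holding(dist)}
    for tid, iv in holding(prox):
        if tid in dist_tids and iv[0] <= dist < iv[1]:
            return "same-exon"

    for _, pe in holding(prox):
        for tid in dist_tids:
            ivs = tx_exons[tid]
            lo = min(s for s, _ in ivs)
            hi = max(e for _, e in ivs)
            if lo <= pe[0] and pe[1] <= hi and \
                    not any(s < pe[1] and pe[0] < e for s, e in ivs):
                return "skipped-exon"

    for _, pe in holding(prox):
        for tid in dist_tids:
            ivs = tx_exons[tid]
            for x in ivs[:-1]:
                donor = x[1] if gm.strand == "+" else x[0]
                if x[0] < pe[1] and pe[0] < x[1] and pe[0] < donor < pe[1]:
                    return "composite-exon"
    return "composite-exon"  # unclassifiable fallback


def random_gene_model(rng: np.random.Generator):
    """A random multi-isoform gene with a manual downstream extension."""
    from apakit.formats import GeneModel

    strand = "+" if rng.random() < 0.5 else "-"
    n_tx = int(rng.integers(1, 4))
    transcripts = {}
    for t in range(n_tx):
        pos = int(rng.integers(0, 200))
        exons = []
        for _ in range(int(rng.integers(1, 5))):
            length = int(rng.integers(50, 300))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(50, 300))
        if strand == "-":
            exons = exons[::-1]
        transcripts[f"t{t}"] = exons
    gm = GeneModel(gene_id="G", chrom="chr1", strand=strand,
                   transcripts=transcripts)
    if strand == "+":
        gm.extended_end = gm.end + 500
    else:
        gm.extended_end = max(0, gm.start - 500)
    return gm
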