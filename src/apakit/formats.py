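"""Readers/writers for the formats the pipeline touches.

Conventions, applied everywhere:

* internal coordinates are 0-based half-open; GTF I/O is 1-based inclusive;
* exon chains are stored sorted 5'->3' in *transcript* orientation, so the
  first exon of a minus-strand transcript has the highest genomic coordinates;
* soft-clipped bases never contribute to aligned spans.
"""

from __future__ import annotations

import logging
import os
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
import pandas as pd
import pysam
from pyfaidx import Fasta

log = logging.getLogger(__name__)

Interval = tuple[int, int]


@dataclass
class GeneModel:
    """Strand-aware exon structure of one gene with all annotated isoforms."""

    gene_id: str
    chrom: str
    strand: str                                   # '+' or '-'
    transcripts: dict[str, list[Interval]]        # tx id -> exons, 5'->3'
    cds: dict[str, list[Interval]] = field(default_factory=dict)
    utr3: list[Interval] = field(default_factory=list)
    biotype: str = "coding"
    extended_end: int | None = None               # set by site_annotation

    @property
    def start(self) -> int:
        return min(s for exons in self.transcripts.values() for s, _ in exons)

    @property
    def end(self) -> int:
        return max(e for exons in self.transcripts.values() for _, e in exons)

    @property
    def three_prime_end(self) -> int:
        """Genomic coordinate of the annotated 3' end (half-open convention:
        the past-the-end coordinate on '+', the first base on '-')."""
        return self.end if self.strand == "+" else self.start

    def span(self) -> Interval:
        return (self.start, self.end)

    def contains(self, pos: int) -> bool:
        s, e = self.span()
        return s <= pos < e


@dataclass(frozen=True)
class CleavageEvent:
    """A cleavage locus observed in one sample, on the transcript strand."""

    chrom: str
    strand: str          # transcript strand
    position: int        # 0-based genomic coordinate of the cleavage base
    sample: str
    count: int


@dataclass
class AlignedRead:
    chrom: str
    strand: str          # alignment strand
    start: int           # aligned span, soft clips excluded
    end: int
    sample: str


class Genome:
    """Random access to a FASTA genome with strand-aware window extraction."""

    def __init__(self, path: str | Path):
        self._fa = Fasta(str(path), rebuild=True, sequence_always_upper=True)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fa

    @property
    def chroms(self) -> list[str]:
        return list(self._fa.keys())

    def length(self, chrom: str) -> int:
        return len(self._fa[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Plus-strand sequence for [start, end), clipped at chromosome bounds."""
        start = max(0, start)
        end = min(self.length(chrom), end)
        if start >= end:
            return ""
        return str(self._fa[chrom][start:end])

    def transcript_window(self, chrom: str, pos: int, strand: str,
                          up: int, down: int) -> str:
        """Sequence from offset -up to +down (inclusive) around ``pos`` in
        transcript orientation; the base at ``pos`` sits at index ``up`` when
        the window is not truncated by a chromosome edge."""
        if strand == "+":
            return self.fetch(chrom, pos - up, pos + down + 1)
        seq = self.fetch(chrom, pos - down, pos + up + 1)
        return revcomp(seq)


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# GTF

def read_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Parse an Ensembl-style GTF into :class:`GeneModel` objects.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    3'UTRs come from ``three_prime_utr``/``UTR`` records when present and are
    otherwise derived from the CDS end of each coding transcript.
    """
    path = Path(path)
    if path.stat().st_size == 0 or not _has_records(path):
        log.warning("GTF %s contains no feature records", path)
        return {}
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )

    tx_gene: dict[str, str] = {}
    tx_strand: dict[str, str] = {}
    tx_chrom: dict[str, str] = {}
    gene_bio: dict[str, str] = {}
    for t in db.features_of_type("transcript"):
        tid = t.attributes["transcript_id"][0]
        gid = t.attributes["gene_id"][0]
        tx_gene[tid] = gid
        tx_strand[tid] = t.strand
        tx_chrom[tid] = t.seqid
        if t.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {t.strand!r} for transcript {tid}")
        gene_bio.setdefault(gid, _biotype(t))

    exons: dict[str, list[Interval]] = {}
    for ex in db.features_of_type("exon"):
        if "transcript_id" not in ex.attributes:
            raise ValueError(
                f"exon without parent transcript at {ex.seqid}:{ex.start}-{ex.end}")
        tid = ex.attributes["transcript_id"][0]
        if tid not in tx_gene:
            raise ValueError(
                f"exon references unknown transcript {tid!r} at "
                f"{ex.seqid}:{ex.start}-{ex.end}")
        exons.setdefault(tid, []).append((ex.start - 1, ex.end))

    cds: dict[str, list[Interval]] = {}
    for c in db.features_of_type("CDS"):
        tid = c.attributes["transcript_id"][0]
        cds.setdefault(tid, []).append((c.start - 1, c.end))

    utr3: dict[str, list[Interval]] = {}
    for ftype in ("three_prime_utr", "UTR"):
        for u in db.features_of_type(ftype):
            tid = u.attributes["transcript_id"][0]
            utr3.setdefault(tid, []).append((u.start - 1, u.end))

    genes: dict[str, GeneModel] = {}
    for tid, ivs in exons.items():
        gid = tx_gene[tid]
        strand = tx_strand[tid]
        ivs = sorted(ivs)
        if strand == "-":
            ivs = ivs[::-1]
        gm = genes.get(gid)
        if gm is None:
            gm = GeneModel(gene_id=gid, chrom=tx_chrom[tid], strand=strand,
                           transcripts={}, biotype=gene_bio.get(gid, "other"))
            genes[gid] = gm
        elif gm.strand != strand:
            raise ValueError(f"gene {gid} has transcripts on both strands")
        gm.transcripts[tid] = ivs
        if tid in cds:
            gm.cds[tid] = sorted(cds[tid])

    for gid, gm in genes.items():
        utrs: list[Interval] = []
        for tid in gm.transcripts:
            if tid in utr3:
                utrs.extend(_downstream_utrs(utr3[tid], gm, tid))
            elif tid in gm.cds:
                utrs.extend(_utr_from_cds(gm.transcripts[tid], gm.cds[tid],
                                          gm.strand))
        gm.utr3 = _merge(utrs)
    return genes


def _has_records(path: Path) -> bool:
    with open(path) as fh:
        return any(line.strip() and not line.startswith("#") for line in fh)


def _biotype(feature) -> str:
    for key in ("gene_biotype", "gene_type"):
        if key in feature.attributes:
            bt = feature.attributes[key][0]
            if bt == "protein_coding":
                return "coding"
            if bt in ("lncRNA", "lincRNA"):
                return "lncRNA"
            return bt
    return "coding"


def _downstream_utrs(utrs: list[Interval], gm: GeneModel, tid: str) -> list[Interval]:
    """Keep only UTR records 3' of the CDS (generic 'UTR' rows cover both ends)."""
    if tid not in gm.cds:
        return utrs
    if gm.strand == "+":
        cds_end = max(e for _, e in gm.cds[tid])
        return [iv for iv in utrs if iv[0] >= cds_end]
    cds_start = min(s for s, _ in gm.cds[tid])
    return [iv for iv in utrs if iv[1] <= cds_start]


def _utr_from_cds(exons: list[Interval], cds: list[Interval],
                  strand: str) -> list[Interval]:
    """Exonic sequence strictly 3' of the CDS stop, in transcript orientation."""
    out: list[Interval] = []
    if strand == "+":
        cds_end = max(e for _, e in cds)
        for s, e in exons:
            if e > cds_end:
                out.append((max(s, cds_end), e))
    else:
        cds_start = min(s for s, _ in cds)
        for s, e in exons:
            if s < cds_start:
                out.append((s, min(e, cds_start)))
    return [iv for iv in out if iv[0] < iv[1]]


def _merge(ivs: list[Interval]) -> list[Interval]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]


# ---------------------------------------------------------------------------
# Alignments

class AlignmentStream:
    """Iterate aligned reads from SAM/BAM, or pre-extracted cleavage events
    from the tabular dialect (chrom, strand, position, sample, count)."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.skipped: Counter = Counter()
        self.tabular = self.path.suffix in (".tsv", ".txt", ".events")

    def reads(self) -> Iterator[AlignedRead]:
        if self.tabular:
            raise ValueError("tabular dialect yields events, not reads")
        mode = "rb" if self.path.suffix == ".bam" else "r"
        with pysam.AlignmentFile(str(self.path), mode, check_sq=False) as af:
            rg_sample = {
                rg["ID"]: rg.get("SM", rg["ID"])
                for rg in af.header.to_dict().get("RG", [])
            }
            default_sample = self.path.stem
            for rec in af:
                if rec.is_unmapped:
                    self.skipped["unmapped"] += 1
                    continue
                if rec.is_secondary:
                    self.skipped["secondary"] += 1
                    continue
                if rec.is_supplementary:
                    self.skipped["supplementary"] += 1
                    continue
                if rec.reference_end is None:
                    raise ValueError(f"malformed CIGAR for read {rec.query_name}")
                sample = default_sample
                if rec.has_tag("RG"):
                    rg = rec.get_tag("RG")
                    sample = rg_sample.get(rg, rg)
                yield AlignedRead(
                    chrom=rec.reference_name,
                    strand="-" if rec.is_reverse else "+",
                    start=rec.reference_start,
                    end=rec.reference_end,
                    sample=sample,
                )

    def events(self) -> Iterator[CleavageEvent]:
        if not self.tabular:
            raise ValueError("use reads() + pas_atlas extraction for SAM/BAM")
        df = pd.read_csv(self.path, sep="\t", dtype={"chrom": str, "sample": str})
        required = {"chrom", "strand", "position", "sample", "count"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"tabular events missing columns {sorted(missing)}")
        for row in df.itertuples(index=False):
            yield CleavageEvent(row.chrom, row.strand, int(row.position),
                                row.sample, int(row.count))


def read_cleavage_alignments(path: str | Path) -> AlignmentStream:
    return AlignmentStream(path)


# ---------------------------------------------------------------------------
# BED

@dataclass(frozen=True)
class BedInterval:
    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None


def read_intervals_bed(path: str | Path) -> list[BedInterval]:
    """BED3+ reader; overlapping rows are preserved, never merged."""
    out: list[BedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
            out.append(BedInterval(chrom, start, end, name, strand))
    return out


# ---------------------------------------------------------------------------
# Matrices

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Feature x sample TSV with 'NA' missing sentinel; duplicate ids rejected."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                     keep_default_na=False)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated feature ids: {dup}")
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                first = df.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"non-numeric cell at row {first!r}, column {col!r}: "
                    f"{df.loc[first, col]!r}")
            df[col] = coerced
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA")
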