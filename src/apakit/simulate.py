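"""Synthetic 3'-end sequencing data with known ground truth.

The generator emulates the statistical structure of a tumor/normal QuantSeq
REV cohort: multi-site genes with planted proximal/distal polyA sites
(hexamer at a fixed upstream offset), internal-priming decoys at A-rich loci
lacking any signal, same-/composite-/skipped-exon isoform configurations,
planted tumor-vs-normal PSI shifts (predominantly shortening), expression
rank-coupled to PSI, and exponential Cox survival driven by selected genes'
PSI. Identical (config, seed) reproduce every output byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

from .config import DEFAULT_HEXAMERS
from .formats import AlignedRead, GeneModel, revcomp

# offsets are transcript-relative; the cleavage base is offset 0
HEXAMER_OFFSET = -20          # start of the planted AATAAA
DECOY_ARUN = (-3, 9)          # half-open offset range of the planted 12-A run
DECOY_PAD = (-35, -3)         # hexamer-free pattern upstream of a decoy
SANITIZE = (-16, 17)          # A-runs broken around planted sites (plus jitter)
MAX_JITTER = 5


@dataclass
class GeneratorConfig:
    n_genes: int = 200
    fraction_multi: float = 0.75        # genes given a proximal/distal pair
    pair_type_mix: tuple[float, float, float] = (0.50, 0.29, 0.21)
    n_decoys: int = 40
    fraction_switched: float = 0.44     # of multi-site genes
    fraction_shortened: float = 0.88    # of switched genes (rest lengthen)
    delta_psi: float = 0.3              # |planted tumor - normal PSI shift|
    baseline_psi: tuple[float, float] = (0.2, 0.8)
    n_prognostic: int = 2
    survival_beta: float = 8.0          # per-gene Cox log-hazard coefficient
    coupled_fraction: float = 0.4       # genes with PSI-coupled expression
    expression_rho: float = 0.3         # target Spearman magnitude
    chrom: str = "chrS"
    gene_pitch: int = 8_000             # genomic spacing between gene starts
    chrom_length: int | None = None     # default: computed from n_genes
    margin: int = 2_000


@dataclass
class ReadDesign:
    n_pairs: int = 20
    depth: int = 100                    # reads per gene per sample
    depth_distribution: str = "poisson"  # or 'fixed'
    jitter_sd: float = 1.5              # cleavage jitter, clipped to +-5 nt
    decoy_depth: int = 20               # reads per decoy per sample
    read_length: int = 60
    softclip_fraction: float = 0.2      # reads given a 5-nt non-cleavage clip
    between_subject_sd: float = 0.1     # subject-level PSI heterogeneity


@dataclass
class ClinicalConfig:
    baseline_hazard: float = 0.02
    horizon: float = 60.0               # administrative censoring time
    covariate_effects: dict = field(default_factory=dict)
    race_probs: tuple[float, float] = (0.5, 0.5)   # EA, AA
    stage_probs: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)


@dataclass
class SyntheticTruth:
    """Ground truth for every planted feature of a synthetic dataset."""

    planted_sites: list[tuple[str, int, str, str]]  # gene, pos, strand, role
    decoy_loci: list[tuple[int, str]]               # position, strand
    planted_delta_psi: dict[str, float]
    pair_config: dict[str, str]
    survival_betas: dict[str, float]
    expression_coupling: dict[str, float]
    baseline_psi: dict[str, float]
    seed: int
    clip_log: list[tuple[str, str]] = field(default_factory=list)

    def validate(self) -> None:
        per_gene: dict[str, int] = {}
        for gene, _, _, _ in self.planted_sites:
            per_gene[gene] = per_gene.get(gene, 0) + 1
        for gene, d in self.planted_delta_psi.items():
            if abs(d) > 1:
                raise ValueError(f"|delta PSI| > 1 for {gene}")
            if d != 0 and per_gene.get(gene, 0) < 2:
                raise ValueError(f"{gene} has a planted shift but <2 sites")
        site_pos = [p for _, p, _, _ in self.planted_sites]
        for dp, _ in self.decoy_loci:
            if any(abs(dp - sp) < 125 for sp in site_pos):
                raise ValueError(f"decoy at {dp} within 125 nt of a site")


# gene templates in transcript-forward coordinates ---------------------------
# each: (length, transcripts {tid: exons}, cds {tid: intervals}, site offsets)
_TEMPLATES = {
    "same-exon": (
        1800,
        {"t1": [(0, 200), (300, 1800)]},
        {"t1": [(50, 200), (300, 500)]},
        (700, 1200),
    ),
    "composite-exon": (
        2000,
        {"t1": [(0, 400), (1000, 2000)], "t2": [(0, 900)]},
        {},
        (600, 1500),
    ),
    "skipped-exon": (
        2200,
        {"t1": [(0, 300), (1200, 2200)], "t2": [(0, 300), (500, 800)]},
        {},
        (650, 1700),
    ),
    "single": (
        1300,
        {"t1": [(0, 200), (300, 1300)]},
        {"t1": [(50, 200), (300, 500)]},
        (800,),
    ),
}
_DECOY_OFFSET = {"same-exon": 950, "single": 1100}
_DECOY_PATTERN = "CGTCGG"   # no A => can seed no catalogued hexamer


@dataclass
class SyntheticGenome:
    chrom: str
    sequence: np.ndarray                # 1-char unicode array
    genes: dict[str, GeneModel]
    truth: SyntheticTruth
    config: GeneratorConfig

    @property
    def chrom_length(self) -> int:
        return len(self.sequence)

    def fasta_text(self) -> str:
        seq = "".join(self.sequence.tolist())
        lines = [f">{self.chrom}"]
        lines += [seq[i:i + 60] for i in range(0, len(seq), 60)]
        return "\n".join(lines) + "\n"

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.fasta_text())

    def gtf_text(self) -> str:
        rows = []
        for gid in sorted(self.genes):
            gm = self.genes[gid]
            bt = "protein_coding" if gm.biotype == "coding" else gm.biotype
            attrs = f'gene_id "{gid}"; gene_biotype "{bt}";'
            rows.append(self._row("gene", gm.start, gm.end, gm.strand, attrs))
            for tid in sorted(gm.transcripts):
                tattrs = attrs + f' transcript_id "{gid}.{tid}";'
                exons = gm.transcripts[tid]
                ts = min(s for s, _ in exons)
                te = max(e for _, e in exons)
                rows.append(self._row("transcript", ts, te, gm.strand, tattrs))
                for s, e in sorted(exons):
                    rows.append(self._row("exon", s, e, gm.strand, tattrs))
                for s, e in gm.cds.get(tid, []):
                    rows.append(self._row("CDS", s, e, gm.strand, tattrs))
        return "\n".join(rows) + "\n"

    def _row(self, feature, start, end, strand, attrs) -> str:
        # 0-based half-open -> 1-based inclusive
        return "\t".join([self.chrom, "apakit", feature, str(start + 1),
                          str(end), ".", strand, ".", attrs])

    def write_gtf(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.gtf_text())

    def write_truth(self, path) -> None:
        t = self.truth
        rows = [{"gene": g, "position": p, "strand": s, "role": r,
                 "delta_psi": t.planted_delta_psi.get(g, 0.0),
                 "baseline_psi": t.baseline_psi.get(g, float("nan")),
                 "pair_type": t.pair_config.get(g, ""),
                 "survival_beta": t.survival_betas.get(g, 0.0),
                 "expression_rho": t.expression_coupling.get(g, 0.0)}
                for g, p, s, r in t.planted_sites]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


class ChromosomeTooShort(ValueError):
    pass


def _tx_to_genomic(offset_in_tx: int, gstart: int, glen: int, strand: str) -> int:
    return gstart + offset_in_tx if strand == "+" else gstart + glen - 1 - offset_in_tx


def _map_interval(iv, gstart, glen, strand):
    a, b = iv
    if strand == "+":
        return (gstart + a, gstart + b)
    return (gstart + glen - b, gstart + glen - a)


def _set_tx_base(seq: np.ndarray, pos: int, strand: str, base: str) -> None:
    if strand == "+":
        seq[pos] = base
    else:
        seq[pos] = revcomp(base)


def _get_tx_base(seq: np.ndarray, pos: int, strand: str) -> str:
    return str(seq[pos]) if strand == "+" else revcomp(str(seq[pos]))


def _plant_tx_seq(seq: np.ndarray, site: int, strand: str, offset: int,
                  subseq: str) -> None:
    """Write ``subseq`` starting at transcript offset ``offset`` from ``site``."""
    for i, base in enumerate(subseq):
        o = offset + i
        pos = site + o if strand == "+" else site - o
        _set_tx_base(seq, pos, strand, base)


def generate_genome_and_annotation(config: GeneratorConfig | None = None,
                                   seed: int = 0) -> SyntheticGenome:
    """Build a genome FASTA-equivalent, gene models and the planted truth."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)

    needed = config.margin * 2 + config.n_genes * config.gene_pitch
    chrom_length = config.chrom_length or needed
    if chrom_length < needed:
        raise ChromosomeTooShort(
            f"chromosome length {chrom_length} cannot hold {config.n_genes} "
            f"genes at pitch {config.gene_pitch} (needs {needed})")
    max_tpl = max(t[0] for t in _TEMPLATES.values())
    if config.gene_pitch < max_tpl + 200:
        raise ChromosomeTooShort(
            f"gene_pitch {config.gene_pitch} smaller than the largest gene "
            f"template ({max_tpl} nt)")

    seq = rng.choice(np.array(list("ACGT")), size=chrom_length)

    n_multi = int(round(config.n_genes * config.fraction_multi))
    types = []
    mix = np.asarray(config.pair_type_mix, dtype=float)
    mix = mix / mix.sum()
    counts = np.floor(mix * n_multi).astype(int)
    counts[0] += n_multi - counts.sum()
    for t, c in zip(("same-exon", "composite-exon", "skipped-exon"), counts):
        types += [t] * int(c)
    types += ["single"] * (config.n_genes - n_multi)
    rng.shuffle(types)

    genes: dict[str, GeneModel] = {}
    planted: list[tuple[str, int, str, str]] = []
    pair_config: dict[str, str] = {}
    gene_sites: dict[str, list[int]] = {}

    for i, tpl_name in enumerate(types):
        gid = f"G{i + 1:04d}"
        glen, txs, cds, offsets = _TEMPLATES[tpl_name]
        strand = "+" if rng.random() < 0.5 else "-"
        gstart = config.margin + i * config.gene_pitch
        transcripts = {}
        for tid, exons in txs.items():
            mapped = sorted(_map_interval(iv, gstart, glen, strand)
                            for iv in exons)
            if strand == "-":
                mapped = mapped[::-1]
            transcripts[tid] = mapped
        cds_mapped = {tid: sorted(_map_interval(iv, gstart, glen, strand)
                                  for iv in ivs)
                      for tid, ivs in cds.items()}
        gm = GeneModel(gene_id=gid, chrom=config.chrom, strand=strand,
                       transcripts=transcripts, cds=cds_mapped,
                       biotype="coding" if cds else "other")
        genes[gid] = gm

        roles = ("proximal", "distal") if len(offsets) == 2 else ("distal",)
        sites = []
        for off, role in zip(offsets, roles):
            pos = _tx_to_genomic(off, gstart, glen, strand)
            planted.append((gid, pos, strand, role))
            sites.append(pos)
            _plant_site_context(seq, pos, strand)
        gene_sites[gid] = sites
        if tpl_name != "single":
            pair_config[gid] = tpl_name

    # planted shifts: among multi-site genes
    multi = sorted(pair_config)
    n_switch = int(round(len(multi) * config.fraction_switched))
    switched = list(rng.choice(multi, size=n_switch, replace=False))
    n_short = int(round(n_switch * config.fraction_shortened))
    delta: dict[str, float] = {}
    for j, gid in enumerate(switched):
        delta[gid] = config.delta_psi if j < n_short else -config.delta_psi

    baseline = {gid: float(rng.uniform(*config.baseline_psi))
                for gid in sorted(pair_config)}

    # decoys inside same-exon or single-template genes
    hosts = [g for g, t in zip(sorted(genes), types)
             if t in ("same-exon", "single")]
    host_type = {g: t for g, t in zip(sorted(genes), types)}
    if config.n_decoys > len(hosts):
        raise ValueError(
            f"{config.n_decoys} decoys requested but only {len(hosts)} "
            "eligible host genes")
    decoy_hosts = list(rng.choice(hosts, size=config.n_decoys, replace=False))
    decoys: list[tuple[int, str]] = []
    for gid in decoy_hosts:
        gm = genes[gid]
        glen = _TEMPLATES[host_type[gid]][0]
        off = _DECOY_OFFSET[host_type[gid]]
        gstart = gm.start if gm.strand == "+" else gm.end - glen
        pos = _tx_to_genomic(off, gstart, glen, gm.strand)
        _plant_decoy_context(seq, pos, gm.strand)
        decoys.append((pos, gm.strand))

    # prognostic and expression coupling assignments
    betas: dict[str, float] = {}
    for gid in sorted(pair_config)[: config.n_prognostic]:
        betas[gid] = config.survival_beta
    coupling: dict[str, float] = {}
    for gid in multi:
        if rng.random() < config.coupled_fraction:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            coupling[gid] = sign * config.expression_rho

    truth = SyntheticTruth(
        planted_sites=planted, decoy_loci=decoys, planted_delta_psi=delta,
        pair_config=pair_config, survival_betas=betas,
        expression_coupling=coupling, baseline_psi=baseline, seed=seed)
    truth.validate()
    return SyntheticGenome(chrom=config.chrom, sequence=seq, genes=genes,
                           truth=truth, config=config)


def _plant_site_context(seq: np.ndarray, pos: int, strand: str) -> None:
    """Hexamer at the planted offset; no internal-priming signal around the
    site even after +-5 nt cleavage jitter."""
    _plant_tx_seq(seq, pos, strand, HEXAMER_OFFSET, "AATAAA")
    _plant_tx_seq(seq, pos, strand, HEXAMER_OFFSET - 1, "C")
    _plant_tx_seq(seq, pos, strand, HEXAMER_OFFSET + 6, "G")
    # break any A-run of >=5 in the jitter-padded priming window
    lo, hi = SANITIZE
    protected = set(range(HEXAMER_OFFSET - 1, HEXAMER_OFFSET + 7))
    run = 0
    for o in range(lo, hi):
        p = pos + o if strand == "+" else pos - o
        if _get_tx_base(seq, p, strand) == "A":
            run += 1
            if run >= 5 and o not in protected:
                _set_tx_base(seq, p, strand, "C")
                run = 0
        else:
            run = 0


def _plant_decoy_context(seq: np.ndarray, pos: int, strand: str) -> None:
    """A 12-A run across the locus (internal-priming signature robust to +-5
    jitter) under a hexamer-free upstream pattern."""
    lo, hi = DECOY_PAD
    pattern = (_DECOY_PATTERN * 10)[: hi - lo]
    _plant_tx_seq(seq, pos, strand, lo, pattern)
    _plant_tx_seq(seq, pos, strand, DECOY_ARUN[0], "A" * (DECOY_ARUN[1] - DECOY_ARUN[0]))


# ---------------------------------------------------------------------------
# Reads

@dataclass
class SimulatedReads:
    reads: list[AlignedRead]
    metadata: pd.DataFrame              # index: sample; subject, tissue
    psi_intended: pd.DataFrame          # gene x sample PSI used for sampling
    design: ReadDesign
    chrom: str
    chrom_length: int
    softclips: dict[int, int] = field(default_factory=dict)  # read idx -> clip

    def write_sam(self, path) -> None:
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": self.chrom, "LN": self.chrom_length}],
            "RG": [{"ID": s, "SM": s} for s in self.metadata.index],
        }
        with pysam.AlignmentFile(str(path), "wh", header=header) as out:
            for i, r in enumerate(self.reads):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"read{i}"
                clip = self.softclips.get(i, 0)
                matched = r.end - r.start
                a.query_sequence = "A" * (matched + clip)
                a.reference_id = 0
                a.reference_start = r.start
                a.mapping_quality = 60
                a.flag = 16 if r.strand == "-" else 0
                # clip sits on the non-cleavage end of the read
                if r.strand == "-":
                    cig = [(4, clip), (0, matched)] if clip else [(0, matched)]
                else:
                    cig = [(0, matched), (4, clip)] if clip else [(0, matched)]
                a.cigartuples = cig
                a.set_tag("RG", r.sample)
                out.write(a)

    def write_events(self, path) -> None:
        from .atlas import extract_cleavage_loci
        events = extract_cleavage_loci(self.reads, "rev")
        rows = [{"chrom": c, "strand": s, "position": p, "sample": sm,
                 "count": n}
                for (c, s, p), per in sorted(events.items())
                for sm, n in sorted(per.items())]
        pd.DataFrame(rows, columns=["chrom", "strand", "position", "sample",
                                    "count"]).to_csv(path, sep="\t", index=False)

    def write_metadata(self, path) -> None:
        self.metadata.to_csv(path, sep="\t", index_label="sample")


def simulate_reads(syn: SyntheticGenome, design: ReadDesign | None = None,
                   seed: int = 0) -> SimulatedReads:
    """Draw per-sample reads around planted usage under the REV protocol:
    each read aligns antisense to its transcript with the cleavage locus at
    the read's 5' terminus, jittered within +-5 nt of the planted site."""
    design = design or ReadDesign()
    if design.depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    truth = syn.truth

    samples, meta_rows = [], []
    for i in range(design.n_pairs):
        subject = f"S{i + 1:03d}"
        for tissue, tag in (("normal", "N"), ("tumor", "T")):
            sid = f"{subject}{tag}"
            samples.append(sid)
            meta_rows.append({"sample": sid, "subject": subject,
                              "tissue": tissue})
    metadata = pd.DataFrame(meta_rows).set_index("sample")

    sites_by_gene: dict[str, dict[str, tuple[int, str]]] = {}
    for gid, pos, strand, role in truth.planted_sites:
        sites_by_gene.setdefault(gid, {})[role] = (pos, strand)

    reads: list[AlignedRead] = []
    softclips: dict[int, int] = {}
    psi_rows = {}
    clip_log: list[tuple[str, str]] = []

    def emit(pos: int, strand: str, sample: str, n: int) -> None:
        if n <= 0:
            return
        jit = np.clip(np.rint(rng.normal(0.0, design.jitter_sd, size=n)),
                      -MAX_JITTER, MAX_JITTER).astype(int)
        has_clip = rng.random(n) < design.softclip_fraction
        L = design.read_length
        for j, s_clip in zip(jit, has_clip):
            p = int(pos + j)
            if strand == "+":      # transcript +  -> alignment on '-'
                start, end, astrand = max(0, p - L + 1), p + 1, "-"
            else:
                start, end, astrand = p, min(syn.chrom_length, p + L), "+"
            idx = len(reads)
            reads.append(AlignedRead(chrom=syn.chrom, strand=astrand,
                                     start=start, end=end, sample=sample))
            if s_clip:
                softclips[idx] = 5

    subjects = metadata["subject"].to_dict()
    subject_ids = sorted(set(subjects.values()))
    for gid in sorted(sites_by_gene):
        roles = sites_by_gene[gid]
        base = truth.baseline_psi.get(gid)
        delta = truth.planted_delta_psi.get(gid, 0.0)
        eta = dict(zip(subject_ids,
                       rng.normal(0.0, design.between_subject_sd,
                                  size=len(subject_ids))))
        row = {}
        for sample in samples:
            tissue = metadata.loc[sample, "tissue"]
            if design.depth_distribution == "poisson":
                depth = int(rng.poisson(design.depth))
            else:
                depth = design.depth
            if "proximal" in roles:
                psi = base + eta[subjects[sample]] + \
                    (delta if tissue == "tumor" else 0.0)
                clipped = min(1.0, max(0.0, psi))
                if clipped != psi:
                    clip_log.append((gid, sample))
                row[sample] = clipped
                n_prox = int(rng.binomial(depth, clipped)) if depth else 0
                emit(*roles["proximal"], sample, n_prox)
                emit(*roles["distal"], sample, depth - n_prox)
            else:
                emit(*roles["distal"], sample, depth)
        if "proximal" in roles:
            psi_rows[gid] = row

    for pos, strand in truth.decoy_loci:
        for sample in samples:
            n = int(rng.poisson(design.decoy_depth)) if design.decoy_depth else 0
            emit(pos, strand, sample, n)

    truth.clip_log.extend(clip_log)
    psi_intended = pd.DataFrame.from_dict(psi_rows, orient="index",
                                          columns=samples, dtype=float)
    psi_intended = psi_intended.reindex(columns=samples)
    return SimulatedReads(reads=reads, metadata=metadata,
                          psi_intended=psi_intended, design=design,
                          chrom=syn.chrom, chrom_length=syn.chrom_length,
                          softclips=softclips)


def make_cohort_truth(n_genes: int, fraction_switched: float,
                      delta_psi: float, seed: int = 0,
                      fraction_shortened: float = 1.0,
                      baseline_psi: tuple[float, float] = (0.2, 0.8),
                      survival_betas: dict | None = None,
                      expression_coupling: dict | None = None
                      ) -> SyntheticTruth:
    """A statistical-layer truth (usage parameters only, placeholder site
    geometry) for count-level cohort simulation."""
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    baseline = {g: float(rng.uniform(*baseline_psi)) for g in genes}
    n_switch = int(round(n_genes * fraction_switched))
    switched = list(rng.choice(genes, size=n_switch, replace=False))
    n_short = int(round(n_switch * fraction_shortened))
    delta = {g: (delta_psi if j < n_short else -delta_psi)
             for j, g in enumerate(switched)}
    sites = []
    for i, g in enumerate(genes):
        sites.append((g, 1000 * (i + 1), "+", "proximal"))
        sites.append((g, 1000 * (i + 1) + 400, "+", "distal"))
    truth = SyntheticTruth(
        planted_sites=sites, decoy_loci=[], planted_delta_psi=delta,
        pair_config={g: "same-exon" for g in genes},
        survival_betas=dict(survival_betas or {}),
        expression_coupling=dict(expression_coupling or {}),
        baseline_psi=baseline, seed=seed)
    truth.validate()
    return truth


def simulate_pair_counts(truth: SyntheticTruth,
                         design: ReadDesign | None = None, seed: int = 0
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                                    pd.DataFrame]:
    """Count-level shortcut: draw proximal/distal read counts per multi-site
    gene and sample under the same distributional model as
    :func:`simulate_reads` (baseline + subject heterogeneity + planted shift,
    binomial split of a Poisson or fixed depth) without emitting alignments.
    Returns (proximal, distal, metadata, intended PSI)."""
    design = design or ReadDesign()
    rng = np.random.default_rng(seed)
    meta_rows = []
    for i in range(design.n_pairs):
        subject = f"S{i + 1:03d}"
        for tissue, tag in (("normal", "N"), ("tumor", "T")):
            meta_rows.append({"sample": f"{subject}{tag}", "subject": subject,
                              "tissue": tissue})
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    samples = list(metadata.index)

    genes = sorted(truth.baseline_psi)
    prox, dist, intended = {}, {}, {}
    subjects = metadata["subject"].to_dict()
    subject_ids = sorted(set(subjects.values()))
    for gid in genes:
        base = truth.baseline_psi[gid]
        delta = truth.planted_delta_psi.get(gid, 0.0)
        eta = dict(zip(subject_ids,
                       rng.normal(0.0, design.between_subject_sd,
                                  size=len(subject_ids))))
        p_row, d_row, i_row = {}, {}, {}
        for sample in samples:
            psi = base + eta[subjects[sample]] + \
                (delta if metadata.loc[sample, "tissue"] == "tumor" else 0.0)
            psi = min(1.0, max(0.0, psi))
            depth = (int(rng.poisson(design.depth))
                     if design.depth_distribution == "poisson"
                     else design.depth)
            k = int(rng.binomial(depth, psi)) if depth else 0
            p_row[sample], d_row[sample], i_row[sample] = k, depth - k, psi
        prox[gid], dist[gid], intended[gid] = p_row, d_row, i_row
    to_df = lambda d: pd.DataFrame.from_dict(d, orient="index",
                                             columns=samples, dtype=float)
    return to_df(prox), to_df(dist), metadata, to_df(intended)


def beta_for_group_hr(hr: float, psi_sd: float) -> float:
    """Cox coefficient planting roughly ``hr`` between the halves of a
    median split on one gene's PSI. For normal heterogeneity the top/bottom
    half means differ by 2*sqrt(2/pi)*sd, so beta = ln(hr) / that gap."""
    gap = 2 * np.sqrt(2 / np.pi) * psi_sd
    return float(np.log(hr) / gap)


# ---------------------------------------------------------------------------
# Clinical and expression layers

def simulate_clinical(truth: SyntheticTruth, psi: pd.DataFrame,
                      config: ClinicalConfig | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Survival and covariates per sample (columns of ``psi``) from an
    exponential Cox model with linear predictor sum(beta_g * PSI_g) plus any
    configured covariate effects; administrative censoring at the horizon."""
    config = config or ClinicalConfig()
    rng = np.random.default_rng(seed)
    samples = list(psi.columns)
    n = len(samples)

    age = rng.normal(65, 8, size=n).round(1)
    sex = rng.choice(["male", "female"], size=n)
    race = rng.choice(["EA", "AA"], size=n, p=config.race_probs)
    stages = [f"stage{r}" for r in ("I", "II", "III", "IV")][: len(config.stage_probs)]
    stage = rng.choice(stages, size=n, p=config.stage_probs)
    smoking = rng.choice(["ever", "never"], size=n)

    lp = np.zeros(n)
    for gene, beta in truth.survival_betas.items():
        if gene in psi.index:
            vals = psi.loc[gene].to_numpy(dtype=float)
            lp += beta * np.nan_to_num(vals, nan=float(np.nanmean(vals)))
    eff = config.covariate_effects
    lp += eff.get("age", 0.0) * (age - age.mean())
    lp += eff.get("male", 0.0) * (sex == "male")

    times = rng.exponential(1.0 / (config.baseline_hazard * np.exp(lp)))
    event = (times <= config.horizon).astype(int)
    times = np.minimum(times, config.horizon)

    return pd.DataFrame({
        "time": times, "event": event, "age": age, "sex": sex,
        "race": race, "stage": stage, "smoking": smoking,
    }, index=pd.Index(samples, name="sample"))


def simulate_expression_protein(truth: SyntheticTruth, psi: pd.DataFrame,
                                seed: int = 0, corr_range=(0.2, 0.8),
                                corr_noise_sd: float = 0.05,
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression rank-coupled to PSI per gene (Gaussian copula hitting the
    target Spearman Rho), plus a per-gene mRNA-protein correlation increasing
    in median PSI through a linear monotone map with additive noise."""
    rng = np.random.default_rng(seed)
    genes = [g for g in psi.index]
    n = psi.shape[1]
    expr = pd.DataFrame(index=psi.index, columns=psi.columns, dtype=float)

    for gid in genes:
        rho = truth.expression_coupling.get(gid, 0.0)
        if abs(rho) > 1:
            raise ValueError(f"target |Rho| > 1 for {gid}")
        vals = psi.loc[gid].to_numpy(dtype=float)
        base_expr = rng.lognormal(mean=3.0, sigma=0.5, size=n)
        if np.isnan(vals).all():
            expr.loc[gid] = base_expr
            continue
        ranks = pd.Series(vals).rank(method="average").to_numpy()
        if abs(rho) == 1.0:
            ordered = np.sort(base_expr)
            idx = (ranks - 1).astype(int)
            expr.loc[gid] = ordered[idx] if rho > 0 else ordered[::-1][idx]
            continue
        # Pearson on normal scores that yields the target Spearman rho
        r = 2 * np.sin(np.pi * rho / 6)
        z = (ranks - ranks.mean()) / max(ranks.std(), 1e-12)
        latent = r * z + np.sqrt(1 - r ** 2) * rng.normal(size=n)
        expr.loc[gid] = np.exp(3.0 + 0.5 * latent)

    med = psi.median(axis=1)
    lo, hi = corr_range
    order = med.rank(method="average")
    frac = (order - 1) / max(len(order) - 1, 1)
    corr = lo + (hi - lo) * frac + rng.normal(0, corr_noise_sd, size=len(med))
    corr = corr.clip(-1, 1)
    protein = pd.DataFrame({"median_psi": med, "mrna_protein_corr": corr})
    return expr, protein
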