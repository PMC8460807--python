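import numpy as np
import pandas as pd
import pytest
from scipy import stats

from apakit.atlas import extract_cleavage_loci, is_internal_priming, \
    find_hexamer
from apakit.config import AtlasConfig
from apakit.formats import Genome, read_cleavage_alignments, read_gene_models
from apakit.simulate import (ChromosomeTooShort, ClinicalConfig,
                             GeneratorConfig, ReadDesign,
                             generate_genome_and_annotation, make_cohort_truth,
                             simulate_clinical, simulate_expression_protein,
                             simulate_pair_counts, simulate_reads)


SMALL = GeneratorConfig(n_genes=20, n_decoys=5)


def test_generation_is_deterministic(tmp_path):
    a = generate_genome_and_annotation(SMALL, seed=1)
    b = generate_genome_and_annotation(SMALL, seed=1)
    assert a.fasta_text() == b.fasta_text()
    assert a.gtf_text() == b.gtf_text()
    assert a.truth == b.truth
    c = generate_genome_and_annotation(SMALL, seed=2)
    assert c.fasta_text() != a.fasta_text()


def test_reads_are_deterministic(tmp_path):
    syn = generate_genome_and_annotation(SMALL, seed=1)
    r1 = simulate_reads(syn, ReadDesign(n_pairs=3, depth=30), seed=5)
    r2 = simulate_reads(syn, ReadDesign(n_pairs=3, depth=30), seed=5)
    p1, p2 = tmp_path / "a.sam", tmp_path / "b.sam"
    r1.write_sam(p1)
    r2.write_sam(p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_degenerate_single_gene_config():
    cfg = GeneratorConfig(n_genes=1, fraction_multi=0.0, n_decoys=0)
    syn = generate_genome_and_annotation(cfg, seed=7)
    assert len(syn.genes) == 1
    assert len(syn.truth.planted_sites) == 1
    assert syn.truth.planted_delta_psi == {}


def test_chromosome_too_short_raises():
    cfg = GeneratorConfig(n_genes=50, chrom_length=10_000)
    with pytest.raises(ChromosomeTooShort):
        generate_genome_and_annotation(cfg, seed=1)


def test_planted_sites_carry_hexamer_and_clean_window(tmp_path):
    syn = generate_genome_and_annotation(SMALL, seed=3)
    syn.write_fasta(tmp_path / "g.fa")
    genome = Genome(tmp_path / "g.fa")
    cfg = AtlasConfig()
    for _, pos, strand, _ in syn.truth.planted_sites:
        assert find_hexamer(genome, syn.chrom, strand, pos, cfg) is not None
        assert not is_internal_priming(genome, syn.chrom, strand, pos, cfg)


def test_decoys_fail_both_filters(tmp_path):
    """Decoy loci must trip the A-run test and lack any catalogued hexamer,
    cross-checked against the real atlas filters."""
    syn = generate_genome_and_annotation(
        GeneratorConfig(n_genes=200, n_decoys=40), seed=3)
    syn.write_fasta(tmp_path / "g.fa")
    genome = Genome(tmp_path / "g.fa")
    cfg = AtlasConfig()
    assert len(syn.truth.decoy_loci) == 40
    for pos, strand in syn.truth.decoy_loci:
        assert is_internal_priming(genome, syn.chrom, strand, pos, cfg)
        assert find_hexamer(genome, syn.chrom, strand, pos, cfg) is None


def test_truth_invariants():
    syn = generate_genome_and_annotation(SMALL, seed=9)
    truth = syn.truth
    truth.validate()
    site_pos = [p for _, p, _, _ in truth.planted_sites]
    for dp, _ in truth.decoy_loci:
        assert all(abs(dp - sp) >= 125 for sp in site_pos)
    per_gene = {}
    for g, _, _, _ in truth.planted_sites:
        per_gene[g] = per_gene.get(g, 0) + 1
    for g, d in truth.planted_delta_psi.items():
        assert d != 0 and per_gene[g] >= 2


def test_zero_jitter_reads_land_exactly_on_planted_loci():
    syn = generate_genome_and_annotation(SMALL, seed=2)
    sim = simulate_reads(syn, ReadDesign(n_pairs=2, depth=20, jitter_sd=0.0,
                                         decoy_depth=5), seed=3)
    events = extract_cleavage_loci(sim.reads, "rev")
    allowed = {(p, s) for _, p, s, _ in syn.truth.planted_sites}
    allowed |= {(p, s) for p, s in syn.truth.decoy_loci}
    for (chrom, strand, pos) in events:
        assert (pos, strand) in allowed


def test_zero_depth_gives_no_gene_reads():
    syn = generate_genome_and_annotation(SMALL, seed=2)
    sim = simulate_reads(syn, ReadDesign(n_pairs=2, depth=0,
                                         depth_distribution="fixed",
                                         decoy_depth=0), seed=3)
    assert sim.reads == []


def test_rev_protocol_read_orientation():
    syn = generate_genome_and_annotation(
        GeneratorConfig(n_genes=4, n_decoys=0), seed=4)
    sim = simulate_reads(syn, ReadDesign(n_pairs=1, depth=10, jitter_sd=0.0,
                                         decoy_depth=0), seed=5)
    strand_of = {p: s for _, p, s, _ in syn.truth.planted_sites}
    for r in sim.reads:
        # read aligns antisense to the transcript; cleavage base at its 5' end
        if r.strand == "-":
            assert strand_of[r.end - 1] == "+"
        else:
            assert strand_of[r.start] == "-"


def test_empirical_psi_close_to_planted_at_high_depth():
    truth = make_cohort_truth(1, 0.0, 0.0, seed=1)
    gid = next(iter(truth.baseline_psi))
    truth.baseline_psi[gid] = 0.5
    prox, dist, meta, intended = simulate_pair_counts(
        truth, ReadDesign(n_pairs=1, depth=10_000, between_subject_sd=0.0,
                          depth_distribution="fixed"), seed=2)
    psi = prox / (prox + dist)
    assert abs(psi.iloc[0, 0] - 0.5) < 0.02


def test_written_outputs_parse_through_formats(tmp_path):
    syn = generate_genome_and_annotation(SMALL, seed=6)
    sim = simulate_reads(syn, ReadDesign(n_pairs=2, depth=15), seed=7)
    syn.write_fasta(tmp_path / "g.fa")
    syn.write_gtf(tmp_path / "a.gtf")
    sim.write_sam(tmp_path / "r.sam")
    sim.write_events(tmp_path / "r.events")
    genes = read_gene_models(tmp_path / "a.gtf")
    assert set(genes) == set(syn.genes)
    for gid, gm in genes.items():
        assert gm.transcripts.keys() == \
            {f"{gid}.{t}" for t in syn.genes[gid].transcripts}
    genome = Genome(tmp_path / "g.fa")
    assert genome.length(syn.chrom) == syn.chrom_length
    reads = list(read_cleavage_alignments(tmp_path / "r.sam").reads())
    assert len(reads) == len(sim.reads)
    events = list(read_cleavage_alignments(tmp_path / "r.events").events())
    assert sum(e.count for e in events) == len(sim.reads)


# ---------------------------------------------------------------------------
# clinical layer

def test_null_betas_give_psi_independent_survival():
    truth = make_cohort_truth(5, 0.0, 0.0, seed=1)
    prox, dist, meta, intended = simulate_pair_counts(
        truth, ReadDesign(n_pairs=100), seed=2)
    pvals = []
    for s in range(40):
        clin = simulate_clinical(truth, intended, ClinicalConfig(), seed=s)
        gene0 = intended.iloc[0]
        groups = gene0 > gene0.median()
        from lifelines.statistics import logrank_test
        r = logrank_test(clin.loc[groups.values, "time"],
                         clin.loc[~groups.values, "time"],
                         event_observed_A=clin.loc[groups.values, "event"],
                         event_observed_B=clin.loc[~groups.values, "event"])
        pvals.append(r.p_value)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_zero_horizon_censors_everyone():
    truth = make_cohort_truth(3, 0.0, 0.0, seed=1)
    psi = pd.DataFrame(0.5, index=list(truth.baseline_psi),
                       columns=[f"s{i}" for i in range(10)])
    clin = simulate_clinical(truth, psi, ClinicalConfig(horizon=0.0), seed=2)
    assert (clin["event"] == 0).all()
    assert (clin["time"] == 0.0).all()


def test_planted_beta_drives_survival():
    truth = make_cohort_truth(5, 0.0, 0.0, seed=1,
                              survival_betas={"G0001": 8.0})
    hits = 0
    for s in range(10):
        prox, dist, meta, intended = simulate_pair_counts(
            truth, ReadDesign(n_pairs=200), seed=100 + s)
        clin = simulate_clinical(truth, intended, ClinicalConfig(),
                                 seed=200 + s)
        gene = intended.loc["G0001"]
        groups = (gene > gene.median()).to_numpy()
        from lifelines.statistics import logrank_test
        r = logrank_test(clin.loc[groups, "time"], clin.loc[~groups, "time"],
                         event_observed_A=clin.loc[groups, "event"],
                         event_observed_B=clin.loc[~groups, "event"])
        hits += r.p_value < 0.01
    assert hits >= 9


# ---------------------------------------------------------------------------
# expression layer

def test_unit_coupling_matches_ranks_exactly():
    truth = make_cohort_truth(2, 0.0, 0.0, seed=1,
                              expression_coupling={"G0001": 1.0})
    rng = np.random.default_rng(3)
    psi = pd.DataFrame(rng.uniform(size=(2, 30)),
                       index=["G0001", "G0002"],
                       columns=[f"s{i}" for i in range(30)])
    expr, _ = simulate_expression_protein(truth, psi, seed=4)
    r1 = psi.loc["G0001"].rank()
    r2 = expr.loc["G0001"].rank()
    assert (r1 == r2).all()


def test_zero_coupling_gives_small_rho():
    genes = 100
    truth = make_cohort_truth(genes, 0.0, 0.0, seed=5)
    rng = np.random.default_rng(6)
    psi = pd.DataFrame(rng.uniform(size=(genes, 100)),
                       index=sorted(truth.baseline_psi),
                       columns=[f"s{i}" for i in range(100)])
    expr, _ = simulate_expression_protein(truth, psi, seed=7)
    rhos = [stats.spearmanr(psi.loc[g], expr.loc[g]).statistic
            for g in psi.index]
    assert np.mean(np.abs(rhos) < 0.25) >= 0.95


def test_target_rho_hit_within_tolerance():
    truth = make_cohort_truth(40, 0.0, 0.0, seed=8,
                              expression_coupling={f"G{i + 1:04d}": 0.5
                                                   for i in range(40)})
    rng = np.random.default_rng(9)
    psi = pd.DataFrame(rng.uniform(size=(40, 80)),
                       index=sorted(truth.baseline_psi),
                       columns=[f"s{i}" for i in range(80)])
    expr, _ = simulate_expression_protein(truth, psi, seed=10)
    rhos = [stats.spearmanr(psi.loc[g], expr.loc[g]).statistic
            for g in psi.index]
    assert abs(np.mean(rhos) - 0.5) < 0.1


def test_protein_concordance_increases_with_median_psi():
    truth = make_cohort_truth(60, 0.0, 0.0, seed=11)
    rng = np.random.default_rng(12)
    base = np.linspace(0.1, 0.9, 60)
    psi = pd.DataFrame(base[:, None] + rng.normal(0, 0.02, size=(60, 30)),
                       index=sorted(truth.baseline_psi),
                       columns=[f"s{i}" for i in range(30)])
    _, protein = simulate_expression_protein(truth, psi, seed=13)
    rho = stats.spearmanr(protein["median_psi"],
                          protein["mrna_protein_corr"]).statistic
    assert rho > 0.8


def test_invalid_target_rho_rejected():
    truth = make_cohort_truth(1, 0.0, 0.0, seed=1)
    truth.expression_coupling["G0001"] = 1.5
    psi = pd.DataFrame([[0.5, 0.6]], index=["G0001"], columns=["a", "b"])
    with pytest.raises(ValueError, match="Rho"):
        simulate_expression_protein(truth, psi, seed=1)
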