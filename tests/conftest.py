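from __future__ import annotations

from pathlib import Path

import pytest

from apakit.formats import Genome
from apakit.pipeline import RunPaths, run_pipeline
from apakit.simulate import (GeneratorConfig, ReadDesign,
                             generate_genome_and_annotation, simulate_reads)


def write_genome(tmp_path: Path, sequences: dict[str, str]) -> Genome:
    """Write chrom -> sequence as FASTA and open it for random access."""
    path = tmp_path / "genome.fa"
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")
    return Genome(path)


@pytest.fixture()
def make_genome(tmp_path):
    def _make(sequences: dict[str, str]) -> Genome:
        return write_genome(tmp_path, sequences)
    return _make


@pytest.fixture(scope="session")
def atlas_cohort(tmp_path_factory):
    """Default-scale synthetic cohort (200 genes, 40 decoys, 20 pairs) run
    end-to-end through the SAM alignment path."""
    out = tmp_path_factory.mktemp("atlas_cohort")
    syn = generate_genome_and_annotation(GeneratorConfig(), seed=11)
    sim = simulate_reads(syn, ReadDesign(n_pairs=20, depth=100), seed=12)
    syn.write_fasta(out / "genome.fa")
    syn.write_gtf(out / "annotation.gtf")
    sim.write_sam(out / "alignments.sam")
    sim.write_metadata(out / "metadata.tsv")
    results = run_pipeline(
        RunPaths(genome=out / "genome.fa", annotation=out / "annotation.gtf",
                 alignments=out / "alignments.sam",
                 metadata=out / "metadata.tsv"),
        out / "run")
    return {"syn": syn, "sim": sim, "results": results, "dir": out}
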