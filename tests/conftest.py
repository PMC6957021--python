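"""Shared fixtures: bundled synthetic test sets and random transcript models."""

from __future__ import annotations

import numpy as np
import pytest

from mnvrescue import simdata
from mnvrescue.pipeline import RunConfig, audit_vcf_only, run_pipeline
from mnvrescue.refmodel import ReferenceSequence, Transcript


@pytest.fixture(scope="session")
def table1_bundle(tmp_path_factory):
    """The five-homozygous-MNV bundle: fixture object plus on-disk files."""
    fixture = simdata.build_fixture(simdata.table1_fixture())
    out = tmp_path_factory.mktemp("table1")
    paths = simdata.write_fixture_bundle(fixture, out, "table1")
    return fixture, paths


@pytest.fixture(scope="session")
def table3_bundle(tmp_path_factory):
    """The four-heterozygous-cis-MNV clinical-panel bundle."""
    fixture = simdata.build_fixture(simdata.table3_fixture())
    out = tmp_path_factory.mktemp("table3")
    paths = simdata.write_fixture_bundle(fixture, out, "table3")
    return fixture, paths


@pytest.fixture(scope="session")
def table1_result(table1_bundle, tmp_path_factory):
    fixture, paths = table1_bundle
    out = tmp_path_factory.mktemp("table1_run")
    config = RunConfig(
        reference=paths["fasta"],
        transcripts=paths["transcripts_tsv"],
        vcf=paths["vcf"],
        bam=paths["bam"],
        out_dir=out,
    )
    return run_pipeline(config)


@pytest.fixture(scope="session")
def table3_result(table3_bundle, tmp_path_factory):
    fixture, paths = table3_bundle
    out = tmp_path_factory.mktemp("table3_run")
    config = RunConfig(
        reference=paths["fasta"],
        transcripts=paths["transcripts_tsv"],
        vcf=paths["vcf"],
        bam=paths["bam"],
        out_dir=out,
    )
    return run_pipeline(config)


def random_transcript(
    rng: np.random.Generator,
    n_codons: int = 40,
    n_exons: int = 1,
    strand: str = "+",
    contig: str = "rnd",
) -> tuple[Transcript, ReferenceSequence]:
    """A random intact CDS (Met...stop, no premature stops) embedded in a
    random contig, optionally split over multiple exons."""
    from Bio.Seq import reverse_complement

    codons = [simdata.NON_STOP_CODONS[i]
              for i in rng.integers(0, len(simdata.NON_STOP_CODONS), n_codons)]
    codons[0] = "ATG"
    codons[-1] = "TAA"
    coding = "".join(codons)
    # split coding sequence into exon chunks separated by random introns
    cut_points = sorted(rng.choice(np.arange(1, len(coding)), size=n_exons - 1,
                                   replace=False)) if n_exons > 1 else []
    chunks = []
    prev = 0
    for cut in list(cut_points) + [len(coding)]:
        chunks.append(coding[prev:cut])
        prev = cut
    flank = 50
    parts = ["".join("ACGT"[i] for i in rng.integers(0, 4, flank))]
    cursor = flank
    exon_spans = []  # genomic ascending, in coding-chunk order
    for chunk in chunks:
        # laid down in plus orientation; the whole-contig flip below
        # handles the minus strand
        start = cursor + 1
        parts.append(chunk)
        cursor += len(chunk)
        exon_spans.append((start, cursor))
        intron = "".join("ACGT"[i] for i in rng.integers(0, 4, 20))
        parts.append(intron)
        cursor += len(intron)
    parts.append("".join("ACGT"[i] for i in rng.integers(0, 4, flank)))
    sequence = "".join(parts)
    if strand == "-":
        # chunk order along the genome must be reversed so that reading the
        # exons 3'->5' genomically reconstructs the coding sequence
        n = len(sequence)
        sequence = reverse_complement(sequence)
        exon_spans = [(n - e + 1, n - s + 1) for s, e in exon_spans]
    ref = ReferenceSequence(contig_name=contig, sequence=sequence)
    exons = sorted(exon_spans, reverse=(strand == "-"))
    tx = Transcript(
        transcript_id="TX_RND",
        gene_symbol="RND",
        contig=contig,
        strand=strand,
        cds_exons=exons,
    )
    return tx, ref
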