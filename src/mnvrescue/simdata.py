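"""Deterministic synthetic fixtures: references, transcripts, planted-MNV reads.

The generator builds small synthetic contigs carrying transcripts whose
declared codons reproduce published MNV test cases, then emits error-free
(by default) single-end reads from explicit haplotypes so that every merge
and annotation decision has an exact, known truth.

Two bundled layouts mirror the printed test tables:

* :func:`table1_fixture` — five homozygous MNVs in HNF4A-like transcripts
  at c.838_840 (CTG>TTC), c.1186_1188 (TAA>TGG, the stop codon),
  c.1066_1068 (TCC>AGC), c.1261_1263 (TCT>TGA) and c.1273_1275 (AAG>AGT).
* :func:`table3_fixture` — four heterozygous cis MNVs from a clinical
  panel: INSR Ala752 GCC>TTC, EIF2AK3 Asp615 GAT>TCT, GCK Glu421 GAG>AGG
  and GCK Tyr61 TAC>CAA, the GCK transcript on the minus strand.

Contigs are synthetic; coordinates are chosen so the published c. positions
are reproduced exactly, and a mapping of the published GRCh37 genome
positions is recorded for documentation only. Everything is a pure function
of (spec, seed): the same inputs yield byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pysam
from Bio.Seq import reverse_complement

from . import consequence as cq
from .errors import FixtureSpecError, InputError
from .mnvmerge import MnvRecord, SnvCall
from .refmodel import (
    STOP_CODONS,
    ReferenceSequence,
    Transcript,
    write_fasta,
    write_transcripts_gff3,
    write_transcripts_tsv,
)

_ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
NON_STOP_CODONS = [c for c in _ALL_CODONS if c not in STOP_CODONS]


@dataclass
class PlantedVariant:
    """One MNV (or SNV) to plant: a codon replaced wholesale.

    ``zygosity`` is 'hom' or 'het'; het variants are planted in ``phase``
    'cis' (all alternate bases on one haplotype — a true MNV) or 'trans'
    (alternate bases split across the two haplotypes — must never merge).
    """

    transcript_id: str
    codon_number: int
    wild_type_codon: str
    variant_codon: str
    zygosity: str = "hom"
    phase: str = "cis"

    def __post_init__(self) -> None:
        if len(self.wild_type_codon) != 3 or len(self.variant_codon) != 3:
            raise FixtureSpecError("codons must be 3 bases")
        if self.wild_type_codon == self.variant_codon:
            raise FixtureSpecError("variant codon equals wild type")
        if self.zygosity not in {"hom", "het"}:
            raise FixtureSpecError(f"zygosity must be hom/het, got {self.zygosity}")
        if self.phase not in {"cis", "trans"}:
            raise FixtureSpecError(f"phase must be cis/trans, got {self.phase}")

    @property
    def edited_offsets(self) -> list[int]:
        """0-based codon offsets where variant differs from wild type."""
        return [
            i for i in range(3) if self.wild_type_codon[i] != self.variant_codon[i]
        ]


@dataclass
class TranscriptSpec:
    """Layout of one synthetic transcript.

    ``n_codons`` counts all codons including the terminal stop.
    ``declared_codons`` pins specific codons (wild-type background for
    planted variants); codon 1 is always ATG and codon ``n_codons`` always
    ``stop_codon`` unless explicitly declared. ``downstream_stop_distance``
    places the first in-frame stop of the downstream region exactly that
    many codons past the CDS stop (used by stop-loss fixtures).
    """

    transcript_id: str
    gene_symbol: str
    n_codons: int
    strand: str = "+"
    declared_codons: dict[int, str] = field(default_factory=dict)
    stop_codon: str = "TAA"
    downstream_stop_distance: int | None = None
    downstream_codons: int = 30

    def __post_init__(self) -> None:
        if self.n_codons < 2:
            raise FixtureSpecError("a transcript needs at least 2 codons")
        for n, codon in self.declared_codons.items():
            if not 1 <= n <= self.n_codons:
                raise FixtureSpecError(
                    f"{self.transcript_id}: declared codon {n} outside CDS"
                )
            if len(codon) != 3 or not set(codon) <= set("ACGT"):
                raise FixtureSpecError(f"bad declared codon {codon!r}")
            if n < self.n_codons and codon in STOP_CODONS:
                raise FixtureSpecError(
                    f"{self.transcript_id}: premature stop declared at codon {n}"
                )
        if (
            self.downstream_stop_distance is not None
            and self.downstream_stop_distance > self.downstream_codons
        ):
            raise FixtureSpecError("downstream stop beyond downstream region")


@dataclass
class FixtureSpec:
    """Full description of a synthetic test bundle."""

    contig_name: str
    transcripts: list[TranscriptSpec]
    variants: list[PlantedVariant]
    flank: int = 300
    intergenic_gap: int = 300
    read_length: int = 150
    coverage: int = 30
    error_rate: float = 0.0
    seed: int = 7
    grch37_positions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = {t.transcript_id for t in self.transcripts}
        seen: set[tuple[str, int]] = set()
        for v in self.variants:
            if v.transcript_id not in known:
                raise FixtureSpecError(f"unknown transcript {v.transcript_id}")
            key = (v.transcript_id, v.codon_number)
            if key in seen:
                raise FixtureSpecError(f"two variants at codon {key}")
            seen.add(key)


@dataclass
class TruthSet:
    """What a correct pipeline must recover from the fixture."""

    snvs: list[SnvCall]
    mnvs: list[MnvRecord]
    expected_hgvs: dict[str, tuple[str, str]]  # cluster key -> (hgvs_c, hgvs_p)


@dataclass
class Fixture:
    spec: FixtureSpec
    reference: ReferenceSequence
    transcripts: list[Transcript]
    truth: TruthSet
    haplotypes: tuple[str, str]


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    idx = rng.integers(0, len(NON_STOP_CODONS), size=n)
    return [NON_STOP_CODONS[i] for i in idx]


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def build_fixture(spec: FixtureSpec) -> Fixture:
    """Materialise the reference, transcript models and truth set.

    The reference carries every declared wild-type codon at its declared
    coding position; CDS padding codons introduce no premature stops; the
    downstream region's first in-frame stop lands at the declared distance.
    """
    rng = np.random.default_rng(spec.seed)
    by_tid = {t.transcript_id: t for t in spec.transcripts}
    for v in spec.variants:
        tspec = by_tid[v.transcript_id]
        declared = dict(tspec.declared_codons)
        declared.setdefault(1, "ATG")
        declared.setdefault(tspec.n_codons, tspec.stop_codon)
        if declared.get(v.codon_number, v.wild_type_codon) != v.wild_type_codon:
            raise FixtureSpecError(
                f"{v.transcript_id} codon {v.codon_number}: declared codon "
                f"conflicts with variant wild type {v.wild_type_codon}"
            )

    genome_parts: list[str] = [_random_bases(rng, spec.flank)]
    cursor = spec.flank  # 0-based length so far
    transcripts: list[Transcript] = []

    for tspec in spec.transcripts:
        codons = _random_codons(rng, tspec.n_codons)
        codons[0] = "ATG"
        codons[-1] = tspec.stop_codon
        for n, codon in tspec.declared_codons.items():
            codons[n - 1] = codon
        for v in spec.variants:
            if v.transcript_id == tspec.transcript_id:
                codons[v.codon_number - 1] = v.wild_type_codon
        coding = "".join(codons)

        down_codons = _random_codons(rng, tspec.downstream_codons)
        if tspec.downstream_stop_distance is not None:
            k = tspec.downstream_stop_distance
            down_codons[k - 1] = "TAA"
        downstream = "".join(down_codons)

        if tspec.strand == "+":
            cds_start = cursor + 1
            genome_parts.append(coding)
            cursor += len(coding)
            cds_end = cursor
            genome_parts.append(downstream)
            cursor += len(downstream)
        else:
            genome_parts.append(reverse_complement(downstream))
            cursor += len(downstream)
            cds_start = cursor + 1
            genome_parts.append(reverse_complement(coding))
            cursor += len(coding)
            cds_end = cursor
        genome_parts.append(_random_bases(rng, spec.intergenic_gap))
        cursor += spec.intergenic_gap

        transcripts.append(
            Transcript(
                transcript_id=tspec.transcript_id,
                gene_symbol=tspec.gene_symbol,
                contig=spec.contig_name,
                strand=tspec.strand,
                cds_exons=[(cds_start, cds_end)],
                downstream_sequence=downstream,
            )
        )

    genome_parts.append(_random_bases(rng, spec.flank))
    reference = ReferenceSequence(
        contig_name=spec.contig_name, sequence="".join(genome_parts)
    )

    tx_by_id = {t.transcript_id: t for t in transcripts}
    snvs: list[SnvCall] = []
    mnvs: list[MnvRecord] = []
    expected: dict[str, tuple[str, str]] = {}
    hap0 = list(reference.sequence)
    hap1 = list(reference.sequence)

    for v in spec.variants:
        tx = tx_by_id[v.transcript_id]
        genotype = "hom_alt" if v.zygosity == "hom" else "het"
        members: list[SnvCall] = []
        for j, off in enumerate(v.edited_offsets):
            c_pos = 3 * (v.codon_number - 1) + off + 1
            gpos = tx.cds_to_genomic(c_pos)
            ref_b = v.wild_type_codon[off]
            alt_b = v.variant_codon[off]
            if tx.strand == "-":
                ref_b, alt_b = (
                    reverse_complement(ref_b),
                    reverse_complement(alt_b),
                )
            assert reference.base(gpos) == ref_b
            members.append(
                SnvCall(
                    contig=spec.contig_name,
                    position=gpos,
                    ref_base=ref_b,
                    alt_base=alt_b,
                    genotype=genotype,
                    source_id=f"{spec.contig_name}:{gpos}:{ref_b}>{alt_b}",
                )
            )
            if v.zygosity == "hom":
                hap0[gpos - 1] = alt_b
                hap1[gpos - 1] = alt_b
            elif v.phase == "cis":
                hap1[gpos - 1] = alt_b
            else:  # trans: split alternate alleles across haplotypes
                (hap0 if j % 2 == 0 else hap1)[gpos - 1] = alt_b
        members.sort(key=lambda m: m.position)
        snvs.extend(members)

        if len(members) >= 2 and v.phase == "cis":
            start, end = members[0].position, members[-1].position
            ref_span = reference.fetch(start, end)
            alt_span = list(ref_span)
            for m in members:
                alt_span[m.position - start] = m.alt_base
            phase = "assumed_cis_homozygous" if v.zygosity == "hom" else "cis"
            mnv = MnvRecord(
                contig=spec.contig_name,
                start=start,
                end=end,
                ref_allele=ref_span,
                alt_allele="".join(alt_span),
                members=members,
                phase_status=phase,
            )
            mnvs.append(mnv)
            edits = [
                cq.edit_from_genomic(tx, m.position, m.ref_base, m.alt_base)
                for m in members
            ]
            ann = cq.annotate_variant(tx, reference, edits)
            expected[f"{spec.contig_name}:{start}_{end}"] = (ann.hgvs_c, ann.hgvs_p)

    snvs.sort(key=lambda m: m.position)
    truth = TruthSet(snvs=snvs, mnvs=mnvs, expected_hgvs=expected)
    return Fixture(
        spec=spec,
        reference=reference,
        transcripts=transcripts,
        truth=truth,
        haplotypes=("".join(hap0), "".join(hap1)),
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_reads(
    fixture: Fixture,
    out_dir: str | Path,
    basename: str = "sim",
) -> tuple[Path, Path]:
    """Emit a coordinate-sorted indexed BAM and the component-SNV VCF.

    Single-end reads tile the contig at an even spacing giving the
    requested coverage; each template draws one of the two haplotypes
    (hom sites therefore appear on every overlapping read, het sites on a
    seeded ~50% of templates, cis alternates always co-occurring).
    Alignments are all-match CIGARs with MAPQ 60 and base quality Q40.
    Deterministic: a fixed (spec, seed) yields byte-identical files.
    """
    spec = fixture.spec
    if spec.coverage <= 0:
        raise InputError("coverage must be positive to simulate reads")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 1_000_003)

    contig = spec.contig_name
    length = len(fixture.reference)
    rl = spec.read_length
    if rl > length:
        raise InputError("read length exceeds contig length")
    step = max(1, rl // spec.coverage)
    starts = list(range(1, length - rl + 2, step))  # 1-based, ascending

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": contig, "LN": length}],
        "PG": [{"ID": "mnvrescue-sim", "PN": "mnvrescue", "VN": "0.1.0"}],
    }
    bam_path = out_dir / f"{basename}.bam"
    hap_choice = rng.integers(0, 2, size=len(starts))
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        for i, start in enumerate(starts):
            hap = fixture.haplotypes[hap_choice[i]]
            seq = list(hap[start - 1 : start - 1 + rl])
            if spec.error_rate > 0:
                errs = rng.random(rl) < spec.error_rate
                for j in np.flatnonzero(errs):
                    seq[j] = "ACGT"[(("ACGT".index(seq[j])) + int(rng.integers(1, 4))) % 4]
            read = pysam.AlignedSegment()
            # haplotype-of-origin recorded in the name: the simulator's truth
            read.query_name = f"tpl{i:06d}.h{hap_choice[i]}"
            read.query_sequence = "".join(seq)
            read.flag = 0
            read.reference_id = 0
            read.reference_start = start - 1
            read.mapping_quality = 60
            read.cigartuples = [(0, rl)]
            read.query_qualities = pysam.qualitystring_to_array("I" * rl)
            bam.write(read)
    pysam.index(str(bam_path))

    vcf_path = out_dir / f"{basename}.calls.vcf"
    vheader = pysam.VariantHeader()
    vheader.contigs.add(contig, length=length)
    vheader.formats.add("GT", 1, "String", "Genotype")
    vheader.add_sample("SAMPLE")
    with pysam.VariantFile(str(vcf_path), "w", header=vheader) as vcf:
        for snv in fixture.truth.snvs:
            rec = vheader.new_record(
                contig=contig,
                start=snv.position - 1,
                stop=snv.position,
                alleles=(snv.ref_base, snv.alt_base),
            )
            rec.samples["SAMPLE"]["GT"] = (1, 1) if snv.genotype == "hom_alt" else (0, 1)
            vcf.write(rec)
    return bam_path, vcf_path


def write_fixture_bundle(
    fixture: Fixture, out_dir: str | Path, basename: str = "sim"
) -> dict[str, Path]:
    """Write FASTA (+ .fai), transcript TSV + GFF3, BAM (+ .bai), VCF and
    a truth JSON into a directory. Returns the paths keyed by role."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / f"{basename}.fa"
    write_fasta(fasta, [fixture.reference])
    pysam.faidx(str(fasta))
    tsv = out_dir / f"{basename}.transcripts.tsv"
    write_transcripts_tsv(tsv, fixture.transcripts)
    gff = out_dir / f"{basename}.transcripts.gff3"
    write_transcripts_gff3(gff, fixture.transcripts)
    bam, vcf = simulate_reads(fixture, out_dir, basename=basename)
    truth_json = out_dir / f"{basename}.truth.json"
    truth = {
        "snvs": [asdict(s) for s in fixture.truth.snvs],
        "mnvs": [
            {
                "contig": m.contig,
                "start": m.start,
                "end": m.end,
                "ref_allele": m.ref_allele,
                "alt_allele": m.alt_allele,
                "phase_status": m.phase_status,
            }
            for m in fixture.truth.mnvs
        ],
        "expected_hgvs": fixture.truth.expected_hgvs,
        "grch37_positions": fixture.spec.grch37_positions,
    }
    truth_json.write_text(json.dumps(truth, indent=2) + "\n")
    return {
        "fasta": fasta,
        "transcripts_tsv": tsv,
        "transcripts_gff3": gff,
        "bam": bam,
        "vcf": vcf,
        "truth": truth_json,
    }


# ---------------------------------------------------------------------------
# Bundled layouts
# ---------------------------------------------------------------------------

def table1_fixture(seed: int = 7, zygosity: str = "hom", phase: str = "cis") -> FixtureSpec:
    """Five MNVs in HNF4A-like transcripts (homozygous by default).

    Codon content and c. positions mirror the published simulated set:
    Leu280 CTG>TTC, the *396 stop TAA>TGG (on a second, longer-CDS
    isoform), Ser356 TCC>AGC, Ser421 TCT>TGA and Lys425 AAG>AGT. The
    stop-loss isoform's downstream region places its first in-frame stop
    26 codons past the original stop. Synthetic contig; the published
    GRCh37 positions are recorded as documentation only.
    """
    tx_a = TranscriptSpec(
        transcript_id="NM_175914",
        gene_symbol="HNF4A",
        n_codons=431,
        strand="+",
    )
    tx_b = TranscriptSpec(
        transcript_id="NM_001030004",
        gene_symbol="HNF4A",
        n_codons=396,
        strand="+",
        stop_codon="TAA",
        downstream_stop_distance=26,
    )
    variants = [
        PlantedVariant("NM_175914", 280, "CTG", "TTC", zygosity, phase),
        PlantedVariant("NM_001030004", 396, "TAA", "TGG", zygosity, phase),
        PlantedVariant("NM_175914", 356, "TCC", "AGC", zygosity, phase),
        PlantedVariant("NM_175914", 421, "TCT", "TGA", zygosity, phase),
        PlantedVariant("NM_175914", 425, "AAG", "AGT", zygosity, phase),
    ]
    return FixtureSpec(
        contig_name="sim20",
        transcripts=[tx_a, tx_b],
        variants=variants,
        seed=seed,
        grch37_positions={
            "NM_175914:c.838_840": "20:43052669_43052671",
            "NM_001030004:c.1186_1188": "20:43053017_43053019",
            "NM_175914:c.1066_1068": "20:43056977_43056979",
            "NM_175914:c.1261_1263": "20:43058207_43058209",
            "NM_175914:c.1273_1275": "20:43058219_43058221",
        },
    )


def table3_fixture(seed: int = 11, phase: str = "cis") -> FixtureSpec:
    """Four heterozygous clinical-panel MNVs; the GCK transcript is minus-strand.

    INSR Ala752 GCC>TTC, EIF2AK3 Asp615 GAT>TCT, GCK Glu421 GAG>AGG and
    GCK Tyr61 TAC>CAA. Synthetic transcripts reproduce only the published
    codon numbers and codon contents.
    """
    specs = [
        TranscriptSpec("NM_INSR_syn", "INSR", n_codons=760, strand="+"),
        TranscriptSpec("NM_EIF2AK3_syn", "EIF2AK3", n_codons=620, strand="+"),
        TranscriptSpec("NM_GCK_syn", "GCK", n_codons=470, strand="-"),
    ]
    variants = [
        PlantedVariant("NM_INSR_syn", 752, "GCC", "TTC", "het", phase),
        PlantedVariant("NM_EIF2AK3_syn", 615, "GAT", "TCT", "het", phase),
        PlantedVariant("NM_GCK_syn", 421, "GAG", "AGG", "het", phase),
        PlantedVariant("NM_GCK_syn", 61, "TAC", "CAA", "het", phase),
    ]
    return FixtureSpec(
        contig_name="sim_panel",
        transcripts=specs,
        variants=variants,
        seed=seed,
    )


def wildtype_fixture(seed: int = 3) -> FixtureSpec:
    """A variant-free fixture; a correct pipeline finds zero clusters."""
    return FixtureSpec(
        contig_name="sim_wt",
        transcripts=[TranscriptSpec("NM_WT_syn", "WT", n_codons=200, strand="+")],
        variants=[],
        seed=seed,
    )
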