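"""Cluster nearby SNV calls, phase them from spanning reads, merge cis pairs.

Two heterozygous SNVs form a multi-nucleotide variant only when they lie on
the same haplotype (cis). Phase is read from the sequencing data itself:
templates (a read pair counts once) that physically span both sites either
carry both alternate alleles, both reference alleles, or a mix — the mix
being evidence for trans. Homozygous pairs are necessarily cis and are
merged without read evidence.

Merged records are same-length reference/alternate spans from the first to
the last member position, with unchanged intervening bases retained — the
HGVS delins convention for adjacent substitutions. Trans and ambiguous
clusters are refused, never silently merged.

Coordinates are 1-based inclusive throughout (VCF convention).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .errors import (
    ConsistencyError,
    InputError,
    MergeRefusedError,
    OrderingError,
)
from .refmodel import ReferenceSequence, Transcript

GENOTYPES = ("het", "hom_alt")

PHASE_STATUSES = (
    "cis",
    "trans",
    "ambiguous",
    "assumed_cis_homozygous",
    "unphased_no_reads",
)

#: INFO keys added to emitted VCF headers.
INFO_MEMBERS = "MNV_MEMBERS"
INFO_PHASE = "MNV_PHASE"
INFO_EVIDENCE = "MNV_EVIDENCE"


@dataclass(frozen=True)
class SnvCall:
    """One single-nucleotide variant call lifted from a VCF record."""

    contig: str
    position: int
    ref_base: str
    alt_base: str
    genotype: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.ref_base not in "ACGT" or self.alt_base not in "ACGT":
            raise InputError(f"{self.key()}: alleles must be single bases A/C/G/T")
        if self.ref_base == self.alt_base:
            raise InputError(f"{self.key()}: ref equals alt")
        if self.genotype not in GENOTYPES:
            raise InputError(f"{self.key()}: genotype must be one of {GENOTYPES}")

    def key(self) -> str:
        return f"{self.contig}:{self.position}{self.ref_base}>{self.alt_base}"


@dataclass
class PhaseEvidence:
    """Spanning-template haplotype support counts for a pair of sites.

    Counts refer to distinct read templates; a template whose mates
    disagree at a site, or that carries a third allele or a base-quality
    failure, is routed to ``n_other``.
    """

    n_both_alt: int = 0
    n_alt_ref: int = 0
    n_ref_alt: int = 0
    n_both_ref: int = 0
    n_other: int = 0

    def __post_init__(self) -> None:
        if min(self.n_both_alt, self.n_alt_ref, self.n_ref_alt,
               self.n_both_ref, self.n_other) < 0:
            raise InputError("phase evidence counts must be non-negative")

    @property
    def n_informative(self) -> int:
        """Templates carrying at least one alternate allele (cis/trans informative)."""
        return self.n_both_alt + self.n_alt_ref + self.n_ref_alt

    def swapped(self) -> "PhaseEvidence":
        """The same evidence viewed with the two sites exchanged."""
        return PhaseEvidence(
            n_both_alt=self.n_both_alt,
            n_alt_ref=self.n_ref_alt,
            n_ref_alt=self.n_alt_ref,
            n_both_ref=self.n_both_ref,
            n_other=self.n_other,
        )

    def encode(self) -> str:
        return (
            f"{self.n_both_alt}|{self.n_alt_ref}|{self.n_ref_alt}"
            f"|{self.n_both_ref}|{self.n_other}"
        )


@dataclass
class Cluster:
    """An ordered run of nearby SNV calls with pairwise phase evidence."""

    members: list[SnvCall]
    pair_evidence: list[PhaseEvidence] = field(default_factory=list)
    phase_status: str = "unphased_no_reads"

    def __post_init__(self) -> None:
        if len({m.contig for m in self.members}) > 1:
            raise InputError("cluster members span multiple contigs")
        positions = [m.position for m in self.members]
        if positions != sorted(positions):
            raise OrderingError("cluster members not in ascending position order")

    @property
    def contig(self) -> str:
        return self.members[0].contig

    @property
    def span(self) -> tuple[int, int]:
        return self.members[0].position, self.members[-1].position

    def key(self) -> str:
        lo, hi = self.span
        return f"{self.contig}:{lo}_{hi}"


@dataclass
class MnvRecord:
    """A merged multi-nucleotide variant: same-length REF/ALT span."""

    contig: str
    start: int
    end: int
    ref_allele: str
    alt_allele: str
    members: list[SnvCall]
    phase_status: str
    pair_evidence: list[PhaseEvidence] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ref_allele) != len(self.alt_allele):
            raise InputError("merged REF and ALT must have equal length")
        if len(self.ref_allele) != self.end - self.start + 1:
            raise InputError("merged allele length must equal the genomic span")
        ndiff = sum(a != b for a, b in zip(self.ref_allele, self.alt_allele))
        if ndiff < 2:
            raise InputError("an MNV must differ from the reference at >= 2 positions")

    @property
    def genotype(self) -> str:
        return "hom_alt" if all(m.genotype == "hom_alt" for m in self.members) else "het"


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_candidates(
    calls: list[SnvCall],
    max_gap: int = 1,
    transcripts: list[Transcript] | None = None,
) -> list[Cluster]:
    """Group SNVs that could form an MNV.

    Two calls are linked when the number of reference bases strictly
    between them is <= ``max_gap``, or — if transcripts are supplied —
    when they fall in the same codon of any transcript. Linking is
    transitive; singletons are not clusters. Calls must arrive sorted by
    (contig, position); calls at the identical position (split
    multiallelics) are never linked to each other.
    """
    if max_gap < 0:
        raise InputError(f"max_gap must be >= 0, got {max_gap}")
    keys = [(c.contig, c.position) for c in calls]
    if keys != sorted(keys):
        raise OrderingError("variant calls must be sorted by contig then position")

    def linked(a: SnvCall, b: SnvCall) -> bool:
        if a.contig != b.contig or a.position == b.position:
            return False
        lo, hi = sorted((a.position, b.position))
        if hi - lo - 1 <= max_gap:
            return True
        for t in transcripts or []:
            if t.contig != a.contig:
                continue
            if t.contains(lo) and t.contains(hi):
                if (
                    t.genomic_to_cds(lo).codon_number
                    == t.genomic_to_cds(hi).codon_number
                ):
                    return True
        return False

    clusters: list[Cluster] = []
    run: list[SnvCall] = []
    for call in calls:
        if run and any(linked(prev, call) for prev in run):
            run.append(call)
        else:
            if len(run) >= 2:
                clusters.append(Cluster(members=run))
            run = [call]
    if len(run) >= 2:
        clusters.append(Cluster(members=run))
    return clusters


# ---------------------------------------------------------------------------
# Read-backed phasing
# ---------------------------------------------------------------------------

def _template_bases(
    bam: pysam.AlignmentFile,
    contig: str,
    positions: list[int],
    min_base_quality: int,
    min_mapping_quality: int,
) -> dict[str, dict[int, str | None]]:
    """Base observed per template per site; None marks a quality failure,
    a mate conflict at that site, or a deletion."""
    lo, hi = min(positions), max(positions)
    obs: dict[str, dict[int, str | None]] = {}
    wanted = set(positions)
    for read in bam.fetch(contig, lo - 1, hi):
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.is_duplicate
            or read.mapping_quality < min_mapping_quality
        ):
            continue
        quals = read.query_qualities
        for qpos, rpos in read.get_aligned_pairs(matches_only=True):
            gpos = rpos + 1
            if gpos not in wanted:
                continue
            base = read.query_sequence[qpos].upper()
            if quals is not None and quals[qpos] < min_base_quality:
                base = None
            per = obs.setdefault(read.query_name, {})
            if gpos in per and per[gpos] is not None and per[gpos] != base:
                per[gpos] = None  # overlapping mates disagree
            elif gpos not in per or per[gpos] is None:
                per[gpos] = base if gpos not in per else per[gpos]
            # identical duplicate observation from the mate: keep as-is
    return obs


def collect_phase_evidence(
    alignments: pysam.AlignmentFile | str | Path,
    site_a: SnvCall,
    site_b: SnvCall,
    min_base_quality: int = 20,
    min_mapping_quality: int = 20,
) -> PhaseEvidence:
    """Tally spanning templates by the alleles they carry at two sites.

    Only templates covering both sites with passing base and mapping
    qualities count; overlapping mates are de-duplicated per template;
    third alleles and quality failures go to ``n_other``.
    """
    if site_a.contig != site_b.contig:
        raise InputError("phase evidence requires both sites on one contig")
    close = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments))
        close = True
    try:
        if not alignments.has_index():
            raise InputError(
                "alignment file must be coordinate-sorted and indexed for random access"
            )
        obs = _template_bases(
            alignments,
            site_a.contig,
            [site_a.position, site_b.position],
            min_base_quality,
            min_mapping_quality,
        )
    finally:
        if close:
            alignments.close()

    ev = PhaseEvidence()
    for per in obs.values():
        if site_a.position not in per or site_b.position not in per:
            continue  # does not span both sites
        ba, bb = per[site_a.position], per[site_b.position]
        if ba is None or bb is None:
            ev.n_other += 1
        elif ba == site_a.alt_base and bb == site_b.alt_base:
            ev.n_both_alt += 1
        elif ba == site_a.alt_base and bb == site_b.ref_base:
            ev.n_alt_ref += 1
        elif ba == site_a.ref_base and bb == site_b.alt_base:
            ev.n_ref_alt += 1
        elif ba == site_a.ref_base and bb == site_b.ref_base:
            ev.n_both_ref += 1
        else:
            ev.n_other += 1
    return ev


def classify_phase(
    evidence: PhaseEvidence,
    genotypes: tuple[str, str],
    min_support: int = 3,
    max_conflict_fraction: float = 0.1,
) -> str:
    """Call cis/trans/ambiguous from spanning-template counts.

    A hom/hom pair is necessarily cis (``assumed_cis_homozygous``)
    regardless of evidence. Otherwise cis requires ``n_both_alt >=
    min_support`` with the mixed-template fraction of informative
    templates <= ``max_conflict_fraction``; trans is the mirrored
    condition on mixed templates; zero informative templates means
    ``unphased_no_reads``; anything else is ambiguous.
    """
    if min_support < 1:
        raise InputError(f"min_support must be >= 1, got {min_support}")
    if not 0 <= max_conflict_fraction < 0.5:
        raise InputError(
            f"max_conflict_fraction must be in [0, 0.5), got {max_conflict_fraction}"
        )
    for g in genotypes:
        if g not in GENOTYPES:
            raise InputError(f"unknown genotype {g!r}")
    if genotypes[0] == "hom_alt" and genotypes[1] == "hom_alt":
        return "assumed_cis_homozygous"
    informative = evidence.n_informative
    if informative == 0:
        return "unphased_no_reads"
    mixed = evidence.n_alt_ref + evidence.n_ref_alt
    if evidence.n_both_alt >= min_support and mixed / informative <= max_conflict_fraction:
        return "cis"
    if mixed >= min_support and evidence.n_both_alt / informative <= max_conflict_fraction:
        return "trans"
    return "ambiguous"


def phase_cluster(
    cluster: Cluster,
    alignments: pysam.AlignmentFile | str | Path | None,
    min_support: int = 3,
    max_conflict_fraction: float = 0.1,
    min_base_quality: int = 20,
    min_mapping_quality: int = 20,
) -> Cluster:
    """Fill in pairwise evidence and the overall phase status of a cluster.

    Without alignments (VCF-only audit) only hom/hom pairs can be called;
    everything else is ``unphased_no_reads``. A cluster merges only if
    every adjacent pair is cis-classified: any trans pair marks the whole
    cluster trans, any ambiguous pair demotes it to ambiguous.
    """
    statuses: list[str] = []
    evidences: list[PhaseEvidence] = []
    for a, b in itertools.pairwise(cluster.members):
        if a.genotype == "hom_alt" and b.genotype == "hom_alt":
            ev = (
                collect_phase_evidence(
                    alignments, a, b, min_base_quality, min_mapping_quality
                )
                if alignments is not None
                else PhaseEvidence()
            )
            status = "assumed_cis_homozygous"
        elif alignments is None:
            ev = PhaseEvidence()
            status = "unphased_no_reads"
        else:
            ev = collect_phase_evidence(
                alignments, a, b, min_base_quality, min_mapping_quality
            )
            status = classify_phase(
                ev, (a.genotype, b.genotype), min_support, max_conflict_fraction
            )
        statuses.append(status)
        evidences.append(ev)

    if "trans" in statuses:
        overall = "trans"
    elif "ambiguous" in statuses:
        overall = "ambiguous"
    elif "unphased_no_reads" in statuses:
        overall = "unphased_no_reads"
    elif all(s == "assumed_cis_homozygous" for s in statuses):
        overall = "assumed_cis_homozygous"
    else:
        overall = "cis"
    cluster.pair_evidence = evidences
    cluster.phase_status = overall
    return cluster


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def merge_cluster(cluster: Cluster, reference: ReferenceSequence) -> MnvRecord:
    """Merge a cis cluster into one delins record.

    The span runs from the first to the last member position; intervening
    reference bases are retained; member alt bases are substituted. Trans,
    ambiguous and unphased clusters are refused.
    """
    if cluster.phase_status not in {"cis", "assumed_cis_homozygous"}:
        raise MergeRefusedError(
            f"cluster {cluster.key()} has phase {cluster.phase_status}; "
            "only cis clusters are merged"
        )
    start, end = cluster.span
    ref_span = reference.fetch(start, end)
    alt = list(ref_span)
    for m in cluster.members:
        offset = m.position - start
        if ref_span[offset] != m.ref_base:
            raise ConsistencyError(
                f"{m.key()}: VCF REF {m.ref_base} does not match reference "
                f"base {ref_span[offset]}"
            )
        alt[offset] = m.alt_base
    return MnvRecord(
        contig=cluster.contig,
        start=start,
        end=end,
        ref_allele=ref_span,
        alt_allele="".join(alt),
        members=list(cluster.members),
        phase_status=cluster.phase_status,
        pair_evidence=list(cluster.pair_evidence),
    )


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def load_snv_calls(vcf_path: str | Path) -> list[SnvCall]:
    """Extract biallelic SNV records with a called non-ref genotype.

    Multi-base or symbolic alleles, and records with 0/0 or missing
    genotypes, are ignored here (they pass through unchanged in
    :func:`emit_vcf`).
    """
    calls: list[SnvCall] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            call = _snv_from_record(rec)
            if call is not None:
                calls.append(call)
    return calls


def _snv_from_record(rec: "pysam.VariantRecord") -> SnvCall | None:
    if rec.alts is None or len(rec.alts) != 1:
        return None
    ref, alt = rec.ref, rec.alts[0]
    if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
        return None
    genotype = "hom_alt"
    if rec.samples:
        gt = rec.samples[0].get("GT")
        if gt is None or set(gt) == {None}:
            return None
        alleles = {a for a in gt if a is not None}
        if alleles == {1}:
            genotype = "hom_alt"
        elif 1 in alleles:
            genotype = "het"
        else:
            return None
    return SnvCall(
        contig=rec.chrom,
        position=rec.pos,
        ref_base=ref,
        alt_base=alt,
        genotype=genotype,
        source_id=f"{rec.chrom}:{rec.pos}:{ref}>{alt}",
    )


def _add_mnv_header(header: pysam.VariantHeader) -> None:
    if INFO_MEMBERS not in header.info:
        header.info.add(
            INFO_MEMBERS, ".", "String",
            "Component SNVs of a merged MNV as POSREF>ALT",
        )
    if INFO_PHASE not in header.info:
        header.info.add(
            INFO_PHASE, "1", "String",
            "Phase status of the merged cluster",
        )
    if INFO_EVIDENCE not in header.info:
        header.info.add(
            INFO_EVIDENCE, ".", "String",
            "Per adjacent pair spanning-template counts "
            "both_alt|alt_ref|ref_alt|both_ref|other",
        )


def emit_vcf(
    original_vcf: str | Path,
    merged: list[MnvRecord],
    out_path: str | Path,
) -> None:
    """Write a VCF with component SNVs replaced by their merged delins records.

    Untouched records pass through unchanged (the header gains the MNV_*
    INFO definitions); output is coordinate sorted. A merged record whose
    members are not present in the input raises :class:`ConsistencyError`.
    """
    member_keys = {
        (m.contig, m.position, m.ref_base, m.alt_base)
        for rec in merged
        for m in rec.members
    }
    with pysam.VariantFile(str(original_vcf)) as vcf:
        _add_mnv_header(vcf.header)
        input_keys = set()
        passthrough = []
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else ""
            key = (rec.chrom, rec.pos, rec.ref, alt)
            input_keys.add(key)
            if key not in member_keys:
                passthrough.append(rec)
        missing = member_keys - input_keys
        if missing:
            raise ConsistencyError(
                f"merged members absent from input VCF: {sorted(missing)}"
            )

        new_records = []
        for mrec in merged:
            rec = vcf.header.new_record(
                contig=mrec.contig,
                start=mrec.start - 1,
                stop=mrec.end,
                alleles=(mrec.ref_allele, mrec.alt_allele),
            )
            rec.info[INFO_MEMBERS] = tuple(
                f"{m.position}{m.ref_base}>{m.alt_base}" for m in mrec.members
            )
            rec.info[INFO_PHASE] = mrec.phase_status
            if mrec.pair_evidence:
                rec.info[INFO_EVIDENCE] = tuple(
                    ev.encode() for ev in mrec.pair_evidence
                )
            if list(vcf.header.samples):
                gt = (1, 1) if mrec.genotype == "hom_alt" else (0, 1)
                rec.samples[0]["GT"] = gt
            new_records.append(rec)

        contig_rank = {name: i for i, name in enumerate(vcf.header.contigs)}
        out_records = sorted(
            passthrough + new_records,
            key=lambda r: (contig_rank.get(r.chrom, len(contig_rank)), r.start),
        )
        with pysam.VariantFile(str(out_path), "w", header=vcf.header) as out:
            for rec in out_records:
                out.write(rec)
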