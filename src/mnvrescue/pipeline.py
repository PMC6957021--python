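"""Pipeline orchestration and the naive-vs-merged discordance report.

``run_pipeline`` ties the stages together: load reference/transcripts/VCF,
cluster nearby SNVs, phase each cluster from the BAM, merge cis clusters
into delins records, annotate both the naive per-SNV and the merged view,
and classify the discordance. ``audit_vcf_only`` runs the same logic
without alignments: hom/hom pairs still merge (necessarily cis), while
heterozygous clusters are reported as phase-unconfirmed candidates.

Outputs: a merged VCF, a fixed-column TSV report (diagnostic labs diff
these, so the column order is versioned), and a machine-readable JSON run
summary; progress is logged to stderr.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

from . import consequence as cq
from . import mnvmerge as mm
from .errors import ConsistencyError, InputError, MergeRefusedError
from .refmodel import ReferenceSequence, Transcript, load_fasta, load_transcripts

logger = logging.getLogger("mnvrescue")

#: Versioned column order of the discordance report.
REPORT_COLUMNS = (
    "gene",
    "transcript",
    "contig",
    "start",
    "end",
    "phase_status",
    "merge_status",
    "naive_annotations",
    "merged_hgvs_c",
    "merged_hgvs_p",
    "category",
    "evidence",
)

MERGE_STATUSES = (
    "merged",
    "refused_trans",
    "refused_ambiguous",
    "candidate_phase_unconfirmed",
)


@dataclass
class RunConfig:
    """Paths, thresholds and flags of one pipeline run.

    All coordinates 1-based; thresholds mirror the merge defaults:
    ``max_gap`` reference bases strictly between two SNVs (default 1, so
    SNVs up to 2 bp apart cluster), plus same-codon co-membership when
    ``require_same_codon`` is set; phase calls need ``min_support``
    spanning templates with at most ``max_conflict_fraction`` conflicting.
    """

    reference: Path
    transcripts: Path
    vcf: Path
    bam: Path | None = None
    out_dir: Path = Path(".")
    max_gap: int = 1
    min_support: int = 3
    max_conflict_fraction: float = 0.1
    min_base_quality: int = 20
    min_mapping_quality: int = 20
    require_same_codon: bool = True
    merge_homozygous: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.reference = Path(self.reference)
        self.transcripts = Path(self.transcripts)
        self.vcf = Path(self.vcf)
        self.bam = Path(self.bam) if self.bam is not None else None
        self.out_dir = Path(self.out_dir)
        for p in (self.reference, self.transcripts, self.vcf):
            if not p.exists():
                raise InputError(f"input not found: {p}")
        if self.bam is not None and not self.bam.exists():
            raise InputError(f"input not found: {self.bam}")
        if self.max_gap < 0:
            raise InputError("max_gap must be >= 0")
        if self.min_support < 1:
            raise InputError("min_support must be >= 1")
        if not 0 <= self.max_conflict_fraction < 0.5:
            raise InputError("max_conflict_fraction must be in [0, 0.5)")


@dataclass
class ClusterOutcome:
    cluster: mm.Cluster
    merge_status: str
    mnv: mm.MnvRecord | None = None
    transcript: Transcript | None = None
    record: cq.DiscordanceRecord | None = None


@dataclass
class RunResult:
    merged_vcf: Path
    report_tsv: Path
    summary_json: Path
    outcomes: list[ClusterOutcome] = field(default_factory=list)
    summary: dict = field(default_factory=dict)


def _check_contig_consistency(
    references: dict[str, ReferenceSequence],
    transcripts: list[Transcript],
    calls: list[mm.SnvCall],
    bam: Path | None,
) -> None:
    ref_contigs = set(references)
    for t in transcripts:
        if t.contig not in ref_contigs:
            raise ConsistencyError(
                f"transcript {t.transcript_id} contig {t.contig} absent from reference "
                f"(reference has {sorted(ref_contigs)})"
            )
    for c in calls:
        if c.contig not in ref_contigs:
            raise ConsistencyError(
                f"VCF contig {c.contig} absent from reference ({sorted(ref_contigs)})"
            )
    if bam is not None:
        with pysam.AlignmentFile(str(bam)) as af:
            bam_contigs = set(af.references)
        used = {c.contig for c in calls}
        missing = used - bam_contigs
        if missing:
            raise ConsistencyError(
                f"VCF contigs {sorted(missing)} absent from BAM ({sorted(bam_contigs)})"
            )


def _containing_transcript(
    transcripts: list[Transcript], cluster: mm.Cluster
) -> Transcript | None:
    """First transcript whose CDS contains every member of the cluster."""
    for t in transcripts:
        if t.contig == cluster.contig and all(
            t.contains(m.position) for m in cluster.members
        ):
            return t
    return None


def _annotate_cluster(
    cluster: mm.Cluster,
    transcript: Transcript,
    reference: ReferenceSequence,
) -> tuple[list[cq.Consequence], cq.Consequence]:
    naive = []
    edits = []
    for m in cluster.members:
        e = cq.edit_from_genomic(transcript, m.position, m.ref_base, m.alt_base)
        edits.append(e)
        naive.append(cq.annotate_variant(transcript, reference, [e]))
    merged = cq.annotate_variant(transcript, reference, edits)
    return naive, merged


def _process(config: RunConfig, use_bam: bool) -> RunResult:
    references = load_fasta(config.reference)
    transcripts = load_transcripts(config.transcripts)
    calls = mm.load_snv_calls(config.vcf)
    bam_path = config.bam if use_bam else None
    _check_contig_consistency(references, transcripts, calls, bam_path)
    logger.info("loaded %d SNV calls, %d transcripts", len(calls), len(transcripts))

    clusters = mm.cluster_candidates(
        calls,
        max_gap=config.max_gap,
        transcripts=transcripts if config.require_same_codon else None,
    )
    logger.info("found %d candidate clusters", len(clusters))

    bam = pysam.AlignmentFile(str(bam_path)) if bam_path is not None else None
    outcomes: list[ClusterOutcome] = []
    merged_records: list[mm.MnvRecord] = []
    try:
        for cluster in clusters:
            mm.phase_cluster(
                cluster,
                bam,
                min_support=config.min_support,
                max_conflict_fraction=config.max_conflict_fraction,
                min_base_quality=config.min_base_quality,
                min_mapping_quality=config.min_mapping_quality,
            )
            if (
                cluster.phase_status == "assumed_cis_homozygous"
                and not config.merge_homozygous
            ):
                cluster.phase_status = "unphased_no_reads"
            status_map = {
                "trans": "refused_trans",
                "ambiguous": "refused_ambiguous",
                "unphased_no_reads": "candidate_phase_unconfirmed",
            }
            mergeable = cluster.phase_status in {"cis", "assumed_cis_homozygous"}
            outcome = ClusterOutcome(
                cluster=cluster,
                merge_status="merged" if mergeable else status_map[cluster.phase_status],
            )
            reference = references[cluster.contig]
            if mergeable:
                try:
                    outcome.mnv = mm.merge_cluster(cluster, reference)
                    merged_records.append(outcome.mnv)
                except MergeRefusedError:  # pragma: no cover - guarded above
                    outcome.merge_status = "refused_ambiguous"
            tx = _containing_transcript(transcripts, cluster)
            if tx is not None:
                outcome.transcript = tx
                naive, merged_cq = _annotate_cluster(cluster, tx, reference)
                outcome.record = cq.classify_discordance(
                    naive, merged_cq, cluster_key=cluster.key()
                )
            outcomes.append(outcome)
    finally:
        if bam is not None:
            bam.close()

    config.out_dir.mkdir(parents=True, exist_ok=True)
    merged_vcf = config.out_dir / "merged.vcf"
    mm.emit_vcf(config.vcf, merged_records, merged_vcf)
    report_tsv = config.out_dir / "discordance.tsv"
    _write_report(outcomes, report_tsv)

    n_cat = {}
    for o in outcomes:
        if o.record is not None:
            n_cat[o.record.category] = n_cat.get(o.record.category, 0) + 1
    summary = {
        "n_input_snvs": len(calls),
        "n_clusters": len(clusters),
        "n_merged": len(merged_records),
        "n_refused": sum(o.merge_status.startswith("refused") for o in outcomes),
        "n_unconfirmed": sum(
            o.merge_status == "candidate_phase_unconfirmed" for o in outcomes
        ),
        "categories": n_cat,
        "config": {
            k: str(v) if isinstance(v, Path) else v
            for k, v in dataclasses.asdict(config).items()
        },
    }
    summary_json = config.out_dir / "run_summary.json"
    summary_json.write_text(json.dumps(summary, indent=2) + "\n")
    logger.info(
        "merged %d clusters (%d refused, %d unconfirmed)",
        summary["n_merged"], summary["n_refused"], summary["n_unconfirmed"],
    )
    return RunResult(
        merged_vcf=merged_vcf,
        report_tsv=report_tsv,
        summary_json=summary_json,
        outcomes=outcomes,
        summary=summary,
    )


def _write_report(outcomes: list[ClusterOutcome], path: Path) -> None:
    rows = []
    for o in outcomes:
        lo, hi = o.cluster.span
        rec = o.record
        naive_s = (
            "; ".join(c.description for c in rec.naive) if rec is not None else ""
        )
        rows.append(
            {
                "gene": o.transcript.gene_symbol if o.transcript else "",
                "transcript": o.transcript.transcript_id if o.transcript else "",
                "contig": o.cluster.contig,
                "start": lo,
                "end": hi,
                "phase_status": o.cluster.phase_status,
                "merge_status": o.merge_status,
                "naive_annotations": naive_s,
                "merged_hgvs_c": rec.merged.hgvs_c if rec else "",
                "merged_hgvs_p": rec.merged.hgvs_p if rec else "",
                "category": rec.category if rec else "",
                "evidence": ",".join(ev.encode() for ev in o.cluster.pair_evidence),
            }
        )
    df = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> RunResult:
    """Full pipeline: cluster, phase from the BAM, merge, annotate, report."""
    if config.bam is None:
        raise InputError("run_pipeline requires a BAM; use audit_vcf_only without one")
    return _process(config, use_bam=True)


def audit_vcf_only(config: RunConfig) -> RunResult:
    """VCF-only audit: identical clustering and annotation, no read phasing.

    Hom/hom clusters merge (necessarily cis); heterozygous clusters are
    flagged ``candidate_phase_unconfirmed`` and never merged.
    """
    return _process(config, use_bam=False)
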