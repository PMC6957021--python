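"""Reference sequence and transcript coordinate machinery.

Genomic <-> CDS coordinate mapping, codon extraction and translation for
strand-aware CDS exon models. All coordinates in this module — genomic and
coding alike — are 1-based inclusive, matching VCF and HGVS conventions.

The coding (c.) coordinate counts from the A of the start codon; on the
minus strand it counts from the 3'-most genomic base of the CDS, so codon
sequences are returned reverse-complemented into coding orientation.
Only the standard genetic code (translation table 1) is supported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import seq3

from .errors import InputError, NonCodingError

VALID_BASES = frozenset("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
STOP = "*"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def complement(base: str) -> str:
    """Complement of a single base (1-based alphabet {A,C,G,T,N})."""
    return base.translate(_COMPLEMENT)


def translate(codon: str) -> str:
    """Translate one codon to a three-letter amino acid, or ``"*"`` for stop.

    Standard genetic code only. Codons containing ambiguous bases (N) are
    untranslatable and raise :class:`InputError`.
    """
    codon = codon.upper()
    if len(codon) != 3 or not set(codon) <= {"A", "C", "G", "T"}:
        raise InputError(f"cannot translate codon {codon!r}: need 3 bases from A/C/G/T")
    aa1 = str(Seq(codon).translate(table=1))
    return STOP if aa1 == "*" else seq3(aa1)


@dataclass(frozen=True)
class CdsCoordinate:
    """A 1-based coding coordinate with its codon decomposition.

    ``codon_number = ceil(c/3)``; ``codon_offset = ((c-1) mod 3) + 1``.
    """

    c_position: int
    codon_number: int
    codon_offset: int

    @classmethod
    def from_c(cls, c_position: int) -> "CdsCoordinate":
        codon, offset = cds_to_codon(c_position)
        return cls(c_position=c_position, codon_number=codon, codon_offset=offset)


def cds_to_codon(c_position: int) -> tuple[int, int]:
    """Map a 1-based coding position to (codon_number, codon_offset in {1,2,3})."""
    if c_position < 1:
        raise InputError(f"coding position must be >= 1, got {c_position}")
    return math.ceil(c_position / 3), (c_position - 1) % 3 + 1


@dataclass
class ReferenceSequence:
    """An in-memory reference contig with 1-based addressing.

    The alphabet is restricted to {A,C,G,T,N}; position queries outside
    [1, len] raise :class:`InputError`.
    """

    contig_name: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise InputError(f"reference {self.contig_name} is empty")
        if not set(self.sequence) <= VALID_BASES:
            bad = sorted(set(self.sequence) - VALID_BASES)
            raise InputError(f"reference {self.contig_name} contains invalid bases {bad}")

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based position."""
        if not 1 <= position <= len(self):
            raise InputError(
                f"position {position} outside [1, {len(self)}] on {self.contig_name}"
            )
        return self.sequence[position - 1]

    def fetch(self, start: int, end: int) -> str:
        """Subsequence over a 1-based inclusive interval [start, end]."""
        if start > end:
            raise InputError(f"fetch start {start} > end {end}")
        if not (1 <= start and end <= len(self)):
            raise InputError(
                f"interval {start}-{end} outside [1, {len(self)}] on {self.contig_name}"
            )
        return self.sequence[start - 1 : end]


@dataclass
class Transcript:
    """A strand-aware CDS exon model.

    ``cds_exons`` are 1-based inclusive genomic intervals (start <= end)
    listed 5'->3' in transcript orientation: ascending genomic order on the
    plus strand, descending on the minus strand. The CDS includes the stop
    codon and its total length must be a multiple of 3.

    ``downstream_sequence`` is coding-orientation sequence beyond the stop
    codon (3' UTR and beyond); when empty it is derived from the reference
    on demand (see :meth:`downstream`).
    """

    transcript_id: str
    gene_symbol: str
    contig: str
    strand: str
    cds_exons: list[tuple[int, int]]
    downstream_sequence: str = ""
    _pos_list: list[int] = field(default_factory=list, repr=False, compare=False)
    _pos_index: dict[int, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise InputError(f"{self.transcript_id}: strand must be '+' or '-'")
        if not self.cds_exons:
            raise InputError(f"{self.transcript_id}: no CDS exons")
        spans = sorted(self.cds_exons)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise InputError(f"{self.transcript_id}: overlapping CDS exons")
        for s, e in self.cds_exons:
            if s > e:
                raise InputError(f"{self.transcript_id}: exon start {s} > end {e}")
        pos_list: list[int] = []
        for s, e in self.cds_exons:
            rng = range(s, e + 1) if self.strand == "+" else range(e, s - 1, -1)
            pos_list.extend(rng)
        if len(pos_list) % 3 != 0:
            raise InputError(
                f"{self.transcript_id}: CDS length {len(pos_list)} not a multiple of 3"
            )
        object.__setattr__(self, "_pos_list", pos_list)
        object.__setattr__(self, "_pos_index", {p: i for i, p in enumerate(pos_list)})

    @property
    def cds_length(self) -> int:
        return len(self._pos_list)

    @property
    def n_codons(self) -> int:
        return self.cds_length // 3

    def contains(self, position: int) -> bool:
        """True if the 1-based genomic position is inside the CDS."""
        return position in self._pos_index

    def genomic_to_cds(self, position: int) -> CdsCoordinate:
        """Map a genomic position to its coding coordinate, honoring strand."""
        idx = self._pos_index.get(position)
        if idx is None:
            raise NonCodingError(self.transcript_id, position)
        return CdsCoordinate.from_c(idx + 1)

    def cds_to_genomic(self, c_position: int) -> int:
        """Inverse of :meth:`genomic_to_cds`."""
        if not 1 <= c_position <= self.cds_length:
            raise InputError(
                f"{self.transcript_id}: c.{c_position} outside CDS of length {self.cds_length}"
            )
        return self._pos_list[c_position - 1]

    def coding_sequence(self, reference: ReferenceSequence) -> str:
        """The full CDS in coding orientation (reverse-complemented for minus strand)."""
        if reference.contig_name != self.contig:
            raise InputError(
                f"{self.transcript_id} is on {self.contig}, not {reference.contig_name}"
            )
        bases = [reference.base(p) for p in self._pos_list]
        seq = "".join(bases)
        return seq.translate(_COMPLEMENT) if self.strand == "-" else seq

    def downstream(self, reference: ReferenceSequence, max_bases: int | None = None) -> str:
        """Coding-orientation sequence 3' of the stop codon.

        Uses ``downstream_sequence`` when set, otherwise walks the reference
        past the CDS end (strand-aware) to the contig boundary.
        """
        if self.downstream_sequence:
            seq = self.downstream_sequence
        else:
            last = self._pos_list[-1]
            if self.strand == "+":
                seq = reference.sequence[last:]
            else:
                seq = reverse_complement(reference.sequence[: last - 1])
        return seq[:max_bases] if max_bases is not None else seq


def genomic_to_cds(transcript: Transcript, position: int) -> CdsCoordinate:
    """Map a 1-based genomic position into the transcript's coding coordinates."""
    return transcript.genomic_to_cds(position)


def codon_sequence(
    transcript: Transcript, reference: ReferenceSequence, codon_number: int
) -> str:
    """The 3-base codon in coding orientation; may span an exon junction."""
    if codon_number < 1 or codon_number > transcript.n_codons:
        raise InputError(
            f"{transcript.transcript_id}: codon {codon_number} outside CDS "
            f"({transcript.n_codons} codons)"
        )
    c_start = 3 * (codon_number - 1) + 1
    bases = []
    for c in range(c_start, c_start + 3):
        g = transcript.cds_to_genomic(c)
        b = reference.base(g)
        bases.append(complement(b) if transcript.strand == "-" else b)
    return "".join(bases)


# ---------------------------------------------------------------------------
# I/O: FASTA, transcript TSV, GFF3
# ---------------------------------------------------------------------------

def load_fasta(path: str | Path) -> dict[str, ReferenceSequence]:
    """Read a FASTA file into :class:`ReferenceSequence` objects keyed by contig."""
    refs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        refs[rec.id] = ReferenceSequence(contig_name=rec.id, sequence=str(rec.seq))
    if not refs:
        raise InputError(f"no sequences in FASTA {path}")
    return refs


def write_fasta(path: str | Path, references: Iterable[ReferenceSequence]) -> None:
    records = [
        SeqRecord(Seq(r.sequence), id=r.contig_name, description="")
        for r in references
    ]
    SeqIO.write(records, str(path), "fasta")


TRANSCRIPT_TSV_COLUMNS = (
    "transcript_id",
    "gene_symbol",
    "contig",
    "strand",
    "cds_exons",
    "downstream_sequence",
)


def load_transcripts_tsv(path: str | Path) -> list[Transcript]:
    """Read the flat transcript config.

    Tab-separated with a header row; columns ``transcript_id, gene_symbol,
    contig, strand, cds_exons, downstream_sequence``. ``cds_exons`` is a
    comma-separated list of ``start-end`` 1-based inclusive intervals in
    transcript (5'->3') order; ``downstream_sequence`` is '.' when empty.
    """
    transcripts = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TRANSCRIPT_TSV_COLUMNS:
            raise InputError(
                f"unexpected transcript TSV header in {path}: {header}"
            )
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            tid, gene, contig, strand, exons_s, down = line.split("\t")
            exons = []
            for part in exons_s.split(","):
                s, e = part.split("-")
                exons.append((int(s), int(e)))
            transcripts.append(
                Transcript(
                    transcript_id=tid,
                    gene_symbol=gene,
                    contig=contig,
                    strand=strand,
                    cds_exons=exons,
                    downstream_sequence="" if down == "." else down,
                )
            )
    if not transcripts:
        raise InputError(f"no transcripts in {path}")
    return transcripts


def write_transcripts_tsv(path: str | Path, transcripts: Iterable[Transcript]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRANSCRIPT_TSV_COLUMNS) + "\n")
        for t in transcripts:
            exons = ",".join(f"{s}-{e}" for s, e in t.cds_exons)
            down = t.downstream_sequence or "."
            fh.write(
                f"{t.transcript_id}\t{t.gene_symbol}\t{t.contig}\t{t.strand}\t{exons}\t{down}\n"
            )


def load_transcripts_gff3(path: str | Path) -> list[Transcript]:
    """Read CDS features from a GFF3 file, grouped by their Parent transcript.

    The gene symbol is taken from a ``gene`` attribute on the CDS features
    (falling back to the Parent id). Downstream sequence is not representable
    in GFF3 and is derived from the reference at annotation time.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    grouped: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [cds.id])
        tid = parents[0]
        info = grouped.setdefault(
            tid,
            {
                "gene": cds.attributes.get("gene", [tid])[0],
                "contig": cds.seqid,
                "strand": cds.strand,
                "exons": [],
            },
        )
        info["exons"].append((cds.start, cds.end))
    transcripts = []
    for tid, info in grouped.items():
        exons = sorted(info["exons"], reverse=(info["strand"] == "-"))
        transcripts.append(
            Transcript(
                transcript_id=tid,
                gene_symbol=info["gene"],
                contig=info["contig"],
                strand=info["strand"],
                cds_exons=exons,
            )
        )
    if not transcripts:
        raise InputError(f"no CDS features in {path}")
    return transcripts


def write_transcripts_gff3(path: str | Path, transcripts: Iterable[Transcript]) -> None:
    """Write CDS features (one per exon) with Parent/gene attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in transcripts:
            for i, (s, e) in enumerate(sorted(t.cds_exons), start=1):
                attrs = f"ID=cds-{t.transcript_id}-{i};Parent={t.transcript_id};gene={t.gene_symbol}"
                fh.write(
                    f"{t.contig}\tmnvrescue\tCDS\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


def load_transcripts(path: str | Path) -> list[Transcript]:
    """Dispatch on extension: .gff/.gff3 -> GFF3 reader, otherwise TSV."""
    suffix = Path(path).suffix.lower()
    if suffix in {".gff", ".gff3"}:
        return load_transcripts_gff3(path)
    return load_transcripts_tsv(path)
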