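"""Protein consequences and HGVS c./p. nomenclature for SNVs and merged MNVs.

The core operation applies one or more single-base coding edits *jointly* to
the coding sequence and retranslates the affected codons — the step that
separates a correct MNV annotation from the naive per-SNV annotation a
standard pipeline produces. A discordance classifier then compares the two
and flags clusters whose naive annotation understates (false-negative risk)
or overstates (false-positive risk) the merged consequence.

All coordinates are 1-based inclusive (HGVS/VCF convention). Protein
changes use three-letter amino-acid codes with ``*`` for stop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InputError, NonCodingError, NotAVariantError
from .refmodel import (
    STOP,
    ReferenceSequence,
    Transcript,
    cds_to_codon,
    complement,
    translate,
)

#: Severity ranks used to call diagnostic risk. Configuration, not code:
#: pass a different mapping to classify_discordance to change the policy.
DEFAULT_SEVERITY = {
    "synonymous": 1,
    "stop_retained": 1,
    "missense": 2,
    "start_lost": 4,
    "stop_lost": 4,
    "stop_gained": 4,
}

EFFECT_CLASSES = tuple(DEFAULT_SEVERITY)


@dataclass(frozen=True)
class CdsEdit:
    """A single-base substitution in coding coordinates (coding-strand bases)."""

    c_position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.c_position < 1:
            raise InputError(f"c.{self.c_position}: coding position must be >= 1")
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise InputError(f"c.{self.c_position}{self.ref}>{self.alt}: bases must be A/C/G/T")
        if self.ref == self.alt:
            raise NotAVariantError(
                f"c.{self.c_position}{self.ref}>{self.alt}: alt equals reference"
            )


def edit_from_genomic(
    transcript: Transcript, position: int, ref_base: str, alt_base: str
) -> CdsEdit:
    """Convert a genomic substitution to a coding-strand :class:`CdsEdit`.

    Minus-strand transcripts complement both alleles.
    """
    coord = transcript.genomic_to_cds(position)
    if transcript.strand == "-":
        ref_base, alt_base = complement(ref_base), complement(alt_base)
    return CdsEdit(c_position=coord.c_position, ref=ref_base, alt=alt_base)


@dataclass
class Consequence:
    """The protein-level effect of one or more coding edits.

    ``codon_numbers``, ``ref_codons``, ``alt_codons``, ``ref_aa`` and
    ``alt_aa`` run in parallel over the affected codons. ``effect_class``
    summarises a single-codon change directly; for multi-codon MNVs it is
    the most severe of the per-codon effects. ``extension_length`` is set
    only for stop_lost: the HGVS ``ext*N`` numeral, or None when no
    downstream in-frame stop was found (rendered ``ext*?``).
    """

    effect_class: str
    codon_numbers: list[int]
    ref_codons: list[str]
    alt_codons: list[str]
    ref_aa: list[str]
    alt_aa: list[str]
    hgvs_c: str
    hgvs_p: str
    extension_length: int | None = None
    per_codon_effects: list[str] = field(default_factory=list)

    @property
    def description(self) -> str:
        """Human-readable ``hgvs_c hgvs_p`` pair as printed in reports."""
        return f"{self.hgvs_c} {self.hgvs_p}".strip()

    def outcomes(self) -> set[tuple[int, str]]:
        """Per-codon residue outcomes as (codon_number, alt_aa) pairs."""
        return set(zip(self.codon_numbers, self.alt_aa))


def stop_extension_length(
    transcript: Transcript,
    edited_coding_plus_downstream: str,
    original_stop_codon_number: int,
) -> int | None:
    """HGVS ``ext*N`` numeral after a stop-loss.

    Scans in-frame codons downstream of the abolished stop; N counts from 1
    for the codon immediately after the original stop position. Returns None
    when the available sequence contains no in-frame stop (reported as
    ``ext*?`` rather than failing).
    """
    seq = edited_coding_plus_downstream
    n = 0
    i = original_stop_codon_number * 3
    while i + 3 <= len(seq):
        n += 1
        if seq[i : i + 3] in {"TAA", "TAG", "TGA"}:
            return n
        i += 3
    return None


def _codon_effect(codon_number: int, ref_aa: str, alt_aa: str) -> str:
    if codon_number == 1 and ref_aa == "Met" and alt_aa != "Met":
        return "start_lost"
    if ref_aa == STOP and alt_aa == STOP:
        return "stop_retained"
    if ref_aa == STOP:
        return "stop_lost"
    if alt_aa == STOP:
        return "stop_gained"
    if ref_aa == alt_aa:
        return "synonymous"
    return "missense"


def _protein_change(codon_number: int, ref_aa: str, alt_aa: str,
                    effect: str, ext: int | None) -> str:
    """One codon's protein change, without the ``p.`` prefix."""
    if effect == "start_lost":
        return "Met1?"
    if effect == "stop_retained":
        return f"*{codon_number}*"
    if effect == "stop_lost":
        n = "?" if ext is None else str(ext)
        return f"*{codon_number}{alt_aa}ext*{n}"
    if effect == "stop_gained":
        return f"{ref_aa}{codon_number}*"
    if effect == "synonymous":
        return f"{ref_aa}{codon_number}{ref_aa}"
    return f"{ref_aa}{codon_number}{alt_aa}"


def hgvs_c_string(edits: list[CdsEdit], edited_coding: str) -> str:
    """HGVS coding description: ``c.POSref>alt`` for one edit, otherwise a
    delins spanning first to last edited base (unchanged intervening bases
    included in the inserted sequence)."""
    if len(edits) == 1:
        e = edits[0]
        return f"c.{e.c_position}{e.ref}>{e.alt}"
    start = min(e.c_position for e in edits)
    end = max(e.c_position for e in edits)
    alt_span = edited_coding[start - 1 : end]
    return f"c.{start}_{end}delins{alt_span}"


def annotate_variant(
    transcript: Transcript,
    reference: ReferenceSequence,
    edits: list[CdsEdit],
) -> Consequence:
    """Apply coding edits jointly and retranslate the affected codons.

    A single affected codon yields simple substitution semantics
    (missense/synonymous/stop_gained/...); a lost stop triggers a
    downstream scan for the extension length; multi-codon MNVs report
    per-codon outcomes with the most severe as the headline effect.
    """
    if not edits:
        raise InputError("no edits supplied")
    coding = transcript.coding_sequence(reference)
    seen: set[int] = set()
    for e in edits:
        if e.c_position > len(coding):
            raise NonCodingError(transcript.transcript_id, f"c.{e.c_position}")
        if e.c_position in seen:
            raise InputError(f"duplicate edit at c.{e.c_position}")
        seen.add(e.c_position)
        ref_here = coding[e.c_position - 1]
        if ref_here != e.ref:
            raise InputError(
                f"{transcript.transcript_id} c.{e.c_position}: expected reference "
                f"{e.ref} but coding sequence has {ref_here}"
            )
    edits = sorted(edits, key=lambda e: e.c_position)
    edited = list(coding)
    for e in edits:
        edited[e.c_position - 1] = e.alt
    edited_coding = "".join(edited)

    codon_numbers = sorted({cds_to_codon(e.c_position)[0] for e in edits})
    ref_codons, alt_codons, ref_aas, alt_aas, effects = [], [], [], [], []
    extension = None
    for cn in codon_numbers:
        lo, hi = 3 * (cn - 1), 3 * cn
        rc, ac = coding[lo:hi], edited_coding[lo:hi]
        raa, aaa = translate(rc), translate(ac)
        eff = _codon_effect(cn, raa, aaa)
        if eff == "stop_lost":
            extension = stop_extension_length(
                transcript,
                edited_coding + transcript.downstream(reference),
                cn,
            )
        ref_codons.append(rc)
        alt_codons.append(ac)
        ref_aas.append(raa)
        alt_aas.append(aaa)
        effects.append(eff)

    severity = DEFAULT_SEVERITY
    headline = max(effects, key=lambda e: severity[e])
    if len(codon_numbers) == 1:
        hgvs_p = "p." + _protein_change(
            codon_numbers[0], ref_aas[0], alt_aas[0], effects[0], extension
        )
    else:
        parts = [
            _protein_change(cn, r, a, eff, extension)
            for cn, r, a, eff in zip(codon_numbers, ref_aas, alt_aas, effects)
        ]
        hgvs_p = "p.[" + ";".join(parts) + "]"

    return Consequence(
        effect_class=headline,
        codon_numbers=codon_numbers,
        ref_codons=ref_codons,
        alt_codons=alt_codons,
        ref_aa=ref_aas,
        alt_aa=alt_aas,
        hgvs_c=hgvs_c_string(edits, edited_coding),
        hgvs_p=hgvs_p,
        extension_length=extension,
        per_codon_effects=effects,
    )


CATEGORIES = ("concordant", "false_negative_risk", "false_positive_risk", "changed_effect")


@dataclass
class DiscordanceRecord:
    """Naive-vs-merged comparison for one cis cluster.

    ``category`` follows a severity rule: merged more severe than every
    naive annotation -> false_negative_risk (the naive view understates the
    variant); merged less severe -> false_positive_risk; equal severity but
    a residue outcome absent from the naive annotations -> changed_effect.
    """

    cluster_key: str
    naive: list[Consequence]
    merged: Consequence
    category: str
    severity_naive_max: int
    severity_merged: int


def classify_discordance(
    naive: list[Consequence],
    merged: Consequence,
    cluster_key: str = "",
    severity: dict[str, int] | None = None,
) -> DiscordanceRecord:
    """Compare per-SNV annotations against the merged MNV annotation."""
    if not naive:
        raise InputError("naive consequence list is empty")
    sev = severity or DEFAULT_SEVERITY
    s_naive = max(sev[c.effect_class] for c in naive)
    s_merged = sev[merged.effect_class]
    if s_merged > s_naive:
        category = "false_negative_risk"
    elif s_merged < s_naive:
        category = "false_positive_risk"
    else:
        naive_outcomes = set().union(*(c.outcomes() for c in naive))
        category = "concordant" if merged.outcomes() <= naive_outcomes else "changed_effect"
    return DiscordanceRecord(
        cluster_key=cluster_key,
        naive=naive,
        merged=merged,
        category=category,
        severity_naive_max=s_naive,
        severity_merged=s_merged,
    )
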