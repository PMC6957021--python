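# Methods

## Scope and model

`mnvrescue` corrects a specific, well-defined failure of per-site variant
annotation: two or more single-nucleotide substitutions on the same
haplotype and close enough to interact at the protein level (usually within
one codon) must be interpreted as one deletion-insertion event. The package
does three things: decide *which* SNV calls belong together (clustering),
decide *whether* they are on the same haplotype (read-backed phasing), and
recompute *what* the joint change means for the protein (codon-aware
re-annotation), reporting every cluster where the naive per-SNV view and
the merged view disagree.

Everything operates on 1-based inclusive coordinates, the convention shared
by VCF and HGVS; this is stated on every public interface.

## Clustering

Two SNVs are linked when the number of reference bases strictly between
them is ≤ `max_gap`, default 1 — equivalent to a maximum span of 3 bp,
which captures substitutions at the first and third base of one codon
(e.g. CTG→TTC) while bounding the span. When transcript models are
supplied, SNVs sharing a codon of any transcript are additionally linked
regardless of gap; this is redundant at the default `max_gap` but keeps
within-codon pairs together if `max_gap` is lowered to 0. Linking is
transitive; singletons are not clusters; input must be coordinate-sorted.
Two records at the identical position (a split multiallelic site) are never
linked to each other: two alternate alleles of one site cannot be cis.

## Read-backed phasing

Phase is decided per adjacent pair from sequencing templates that
physically cover both sites. A read pair counts once; if overlapping mates
disagree at a site, or a base fails `min_base_quality` (default 20), or the
read fails `min_mapping_quality` (default 20), or a third allele appears,
the template is routed to an `other` bin and is uninformative. The
informative templates are those carrying at least one alternate allele:

* **cis** — `n_both_alt ≥ min_support` (default 3 templates) and the mixed
  fraction `(n_alt_ref + n_ref_alt) / informative ≤ max_conflict_fraction`
  (default 0.1);
* **trans** — the mirror: mixed templates ≥ `min_support` and
  `n_both_alt / informative ≤ max_conflict_fraction`;
* **unphased** — zero informative templates;
* **ambiguous** — anything else.

The classification is symmetric under exchanging the two sites (swapping
the two mixed counts). The thresholds are deliberately conservative and
fully configurable; they are this package's choices, since correct phasing
behaviour — not a specific threshold — is the requirement.

Two special rules:

* A hom/hom pair is necessarily cis (both haplotypes carry both alternate
  alleles), so it merges without read evidence
  (`assumed_cis_homozygous`); this also makes a VCF-only audit able to
  merge homozygous MNVs. Disable with `merge_homozygous=False`.
* A cluster of ≥ 3 SNVs merges only if *every* adjacent pair is
  cis-classified; one trans pair marks the cluster trans, one ambiguous
  pair demotes it to ambiguous. This avoids constructing chimeric
  haplotypes. Refused clusters are reported, never silently dropped, and
  their component records pass through to the output VCF unchanged.

Quality scores of the component records are *not* aggregated into a merged
quality — there is no principled way to combine them — so the merged record
instead carries its members, phase status and evidence counts in the
`MNV_MEMBERS`, `MNV_PHASE` and `MNV_EVIDENCE` INFO fields
(evidence encoded `both_alt|alt_ref|ref_alt|both_ref|other` per adjacent
pair).

## Consequence annotation

All edits of a cluster are applied jointly to the coding sequence and each
affected codon is retranslated (standard genetic code only; every example
this package targets is a human nuclear gene). Codons spanning exon
junctions are handled by concatenating CDS bases in transcript order.
Effects: synonymous, stop_retained (a stop replaced by a different stop),
missense, stop_gained, stop_lost, start_lost. Any non-synonymous change to
codon 1 is start_lost — no downstream-ATG rescue is attempted, and a stop
created inside the start codon is subsumed under start_lost; both sit at
the same (maximal) severity, so the risk classification is unaffected.

HGVS strings use three-letter amino-acid codes with `*` for stop. A single
SNV is `c.POSref>alt`; a merged MNV is `c.START_ENDdelinsALT` spanning
first to last *edited* base, with unchanged intervening bases included in
the inserted sequence (so CTG→TTC at codon positions 1 and 3 is
`c.838_840delinsTTC`, while an adjacent pair is `c.1066_1067delinsAG`).
Multi-codon MNVs produce one delins `c.` string and a compound protein
allele `p.[...;...]`; only intra-codon cases occur in the bundled fixtures.

**Stop-loss extension.** When the stop codon is abolished, translation
continues into downstream sequence until the next in-frame stop. The
`ext*N` numeral counts codons starting at 1 for the codon immediately
after the original stop position; if the available downstream sequence
contains no in-frame stop the annotation degrades to `ext*?` rather than
failing. This counting convention reproduces the one published worked
example (`p.*396Trpext*26`), but because that check runs against this
package's own synthetic transcript (whose downstream stop is placed at the
published distance by construction) rather than the live RefSeq sequence,
the convention is exercised, not independently validated — a documented
assumption.

**Discordance categories.** The diagnostic-risk call derives from a
severity ranking — `{synonymous: 1, stop_retained: 1, missense: 2,
start_lost: 4, stop_lost: 4, stop_gained: 4}` — passed as configuration,
not hard-coded policy. Merged more severe than the most severe naive
annotation ⇒ `false_negative_risk`; less severe ⇒ `false_positive_risk`;
equal severity with a per-codon residue outcome not present among the
naive outcomes ⇒ `changed_effect`; otherwise `concordant`. The ranking
reflects testing for dominant-acting loss-of-function variants, where a
truncating call is maximally consequential; under it, a naive stop-gain
that merges to a missense (the GCK Tyr61 case) classifies as
false-positive risk. For edits confined to distinct codons the merged
consequence decomposes exactly into the naive ones and the cluster is
concordant; this is asserted as a property test.

## Synthetic data

The simulator exists to make every pipeline decision exactly checkable
offline. A fixture spec declares transcripts (codon count, strand, pinned
codons, downstream-stop distance) and planted variants (codon, wild-type
and variant codon, zygosity, cis or trans phase). The generator embeds an
intact ORF (ATG … stop, no premature in-frame stops) in random flanking
sequence, substitutes the declared codons, and derives the truth set — the
component SNVs, the expected merged records and their expected HGVS
strings — by construction. Generation is pure: the same (spec, seed)
yields byte-identical FASTA/BAM/VCF output.

Reads are single-end 150 bp at 30× coverage, error-free, MAPQ 60, base
quality Q40, emitted pre-aligned with all-match CIGARs by deterministic
tiling (one read start every 5 bp). These are this package's defaults,
chosen so that truth is exact: an error-free homozygous site appears on
every overlapping read, and a heterozygous site on the reads drawn from
the alternate haplotype (a seeded ~50% of templates; the
haplotype-of-origin is recorded in each read name so tests can tally truth
directly). Trans fixtures place the alternate alleles on opposite
haplotypes to exercise the refuse-to-merge path. What the simulator does
*not* model: sequencing error profiles and quality-score distributions,
alignment artefacts (soft-clipping, indel realignment), coverage
variability, duplicates, or indels. Passing tests on these fixtures
therefore demonstrate correctness of the clustering/phasing/merging/
annotation logic, not robustness to noisy real-world alignments — on real
data the quality thresholds and `max_conflict_fraction` do the filtering
work that the simulator never stresses.

The two bundled layouts reproduce published test cases: five homozygous
MNVs in HNF4A-like transcripts (Leu280 CTG→TTC, the *396 stop TAA→TGG on a
second isoform whose downstream region has its first in-frame stop 26
codons out, Ser356 TCC→AGC, Ser421 TCT→TGA, Lys425 AAG→AGT) and four
heterozygous-cis clinical-panel MNVs (INSR Ala752 GCC→TTC, EIF2AK3 Asp615
GAT→TCT, GCK Glu421 GAG→AGG and Tyr61 TAC→CAA, the GCK transcript on the
minus strand). Contigs are synthetic with coordinates chosen to reproduce
the published *coding* positions exactly; the published GRCh37 genomic
positions are recorded in the truth JSON for documentation only, so no
genome download is needed. The synthetic transcripts reproduce only the
published codon numbers and codon contents, not the genes' real sequences.

## Numerical and degenerate-input choices

* Alphabet {A,C,G,T,N}; N is untranslatable and a variant allele may not
  be N. Position queries outside the contig or CDS raise immediately with
  the transcript and position named.
* A cluster member whose VCF REF disagrees with the reference FASTA is a
  cross-file consistency error, as is a contig name present in the VCF but
  absent from the FASTA or BAM.
* The pipeline is idempotent: merged delins records are not SNVs, so
  re-running on its own output finds no clusters.
* Every input record is accounted for exactly once: passed through,
  replaced by a merged record, or reported refused/unconfirmed.
* Report columns are fixed and versioned (`pipeline.REPORT_COLUMNS`)
  because downstream users diff these files; a machine-readable JSON run
  summary is written alongside, and logs go to stderr.

## Problem sizes

The bundled fixtures use contigs of 3.6–7.3 kb with 700–1500 simulated
reads; the multi-seed recovery sweep runs the full pipeline on 20
regenerated bundles, and the annotation property test checks 1000 random
codon/edit cases against a full-retranslation oracle. These sizes make
truth exhaustively checkable while keeping the whole suite fast.

## Known limitations

* SNV–indel merging, statistical/population phasing and splice-site, UTR
  or regulatory consequences are out of scope; so is pathogenicity
  scoring — the package flags annotation discordance, nothing more.
* Only translation table 1; no selenocysteine recoding.
* Merged records carry no aggregate quality score (see above).
* Phase calling needs spanning templates: sites farther apart than the
  template length are unphasable from reads alone and will be reported as
  candidates, not merged (unless homozygous).
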