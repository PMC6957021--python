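# mnvrescue

Rescue multi-nucleotide variants (MNVs) that standard NGS pipelines miscall
as independent SNVs.

## The problem

Two or more SNVs that lie on the same DNA strand within a few bases — often
inside one codon — constitute a single mutational event. HGVS nomenclature
treats adjacent substitutions as one deletion-insertion
(`c.START_ENDdelinsALT`), and the protein consequence must be computed from
the jointly edited codon. Most widely used variant-calling pipelines emit
each SNV separately and annotate each against the unmodified reference, so a
CTG→TTC change (Leu→Phe, missense) is reported as two "synonymous" variants
(CTG→TTG and CTG→CTC). In a diagnostic laboratory that misannotation can
mean a missed pathogenic variant (false negative) or a spurious one (false
positive).

`mnvrescue` post-processes a per-site VCF:

1. **Cluster** SNVs whose inner gap is ≤ `max_gap` reference bases
   (default 1, i.e. ≤ 2 bp apart) or that share a codon of a supplied
   transcript model.
2. **Phase** each cluster from the aligned reads: templates that physically
   span both sites either carry both alternate alleles (cis evidence) or a
   mix (trans evidence). A pair is called cis when
   `n_both_alt ≥ min_support` and the conflicting fraction of informative
   templates is ≤ `max_conflict_fraction`. Homozygous pairs are necessarily
   cis and merge without read evidence; trans and ambiguous clusters are
   refused and reported, never silently merged.
3. **Merge** cis clusters into one same-length delins record
   (`REF=CTG, ALT=TTC`), keeping unchanged intervening bases.
4. **Re-annotate** the merged allele codon-aware — including stop-gain,
   stop-retained and stop-loss with the HGVS `ext*N` extension length — and
   compare against the naive per-SNV annotations.
5. **Classify** the disagreement by a severity ranking
   (synonymous/stop-retained 1 < missense 2 < start-loss/stop-loss/stop-gain 4):
   merged more severe than naive ⇒ *false-negative risk*, less severe ⇒
   *false-positive risk*, equally severe but a different residue ⇒
   *changed effect*.

A bundled simulator generates synthetic references, transcript models,
planted-variant reads (BAM) and truth sets, so the entire pipeline is
testable offline, including the classic five-MNV *HNF4A* test set and four
clinical-panel MNVs (one on a minus-strand transcript).

## Worked example

Generate the five-homozygous-MNV bundle, then ask what two SNVs in the
Leu280 codon mean separately versus jointly:

```sh
mnvrescue fixtures --bundle table1 --out-dir demo
mnvrescue annotate --reference demo/table1.fa \
    --transcripts demo/table1.transcripts.tsv \
    --transcript-id NM_175914 --edits "c.838C>T,c.840G>C"
```

```text
naive  c.838C>T p.Leu280Leu  [synonymous]
naive  c.840G>C p.Leu280Leu  [synonymous]
merged c.838_840delinsTTC p.Leu280Phe  [missense]
category: false_negative_risk
```

Each SNV alone is silent, but on the same haplotype they change the codon
to TTC — a missense that per-SNV annotation would hide entirely
(`false_negative_risk`). Running the full pipeline merges all five planted
MNVs and writes the discordance report:

```sh
mnvrescue merge --reference demo/table1.fa \
    --transcripts demo/table1.transcripts.tsv \
    --vcf demo/table1.calls.vcf --bam demo/table1.bam --out-dir demo/out
```

| gene | naive annotations | merged | category |
|------|-------------------|--------|----------|
| HNF4A | c.838C>T p.Leu280Leu; c.840G>C p.Leu280Leu | c.838_840delinsTTC p.Leu280Phe | false_negative_risk |
| HNF4A | c.1066T>A p.Ser356Thr; c.1067C>G p.Ser356Cys | c.1066_1067delinsAG p.Ser356Ser | false_positive_risk |
| HNF4A | c.1262C>G p.Ser421Cys; c.1263T>A p.Ser421Ser | c.1262_1263delinsGA p.Ser421* | false_negative_risk |
| HNF4A | c.1274A>G p.Lys425Arg; c.1275G>T p.Lys425Asn | c.1274_1275delinsGT p.Lys425Ser | changed_effect |
| HNF4A | c.1187A>G p.*396*; c.1188A>G p.*396* | c.1187_1188delinsGG p.*396Trpext*26 | false_negative_risk |

The last row abolishes a stop codon: separately each SNV leaves a stop in
place (silent), jointly they read through into the 3' UTR until the next
in-frame stop 26 codons downstream.

`mnvrescue audit` runs the same analysis without a BAM (hom/hom pairs still
merge; heterozygous clusters are flagged `candidate_phase_unconfirmed`),
and `mnvrescue merge --help` lists the thresholds (`--max-gap`,
`--min-support`, `--max-conflict-fraction`, quality minima).

## Library surface

```python
from mnvrescue import (
    load_fasta, load_transcripts,          # reference / transcript models
    cluster_candidates, collect_phase_evidence, classify_phase,
    merge_cluster, emit_vcf,               # merging
    annotate_variant, classify_discordance,  # consequences
    RunConfig, run_pipeline, audit_vcf_only,  # orchestration
)
from mnvrescue import simdata              # fixture generator
```

See `docs/methods.md` for the model, parameter rationale and limitations.

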