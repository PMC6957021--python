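"""Clustering, read-backed phase classification, merging, VCF emission."""

from __future__ import annotations

import itertools

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mnvrescue.errors import InputError, MergeRefusedError, OrderingError
from mnvrescue.mnvmerge import (
    Cluster,
    PhaseEvidence,
    SnvCall,
    classify_phase,
    cluster_candidates,
    collect_phase_evidence,
    emit_vcf,
    load_snv_calls,
    merge_cluster,
)
from mnvrescue.refmodel import ReferenceSequence


def snv(pos, ref="A", alt="G", contig="c1", gt="het"):
    return SnvCall(contig=contig, position=pos, ref_base=ref, alt_base=alt, genotype=gt)


class TestClustering:
    def test_inner_gap_one_pair_clusters(self):
        # mirrors a variant pair two bases apart (first and third codon base)
        calls = [snv(2669, "C", "T"), snv(2671, "G", "C")]
        clusters = cluster_candidates(calls, max_gap=1)
        assert len(clusters) == 1 and len(clusters[0].members) == 2

    def test_lone_snv_is_not_a_cluster(self):
        assert cluster_candidates([snv(100)]) == []

    def test_gap_beyond_threshold_splits(self):
        calls = [snv(100, "C", "T"), snv(103, "G", "C")]
        assert cluster_candidates(calls, max_gap=1) == []
        assert len(cluster_candidates(calls, max_gap=2)) == 1

    def test_same_codon_links_regardless_of_gap(self, table1_bundle):
        fixture, _ = table1_bundle
        tx = fixture.transcripts[0]
        ref = fixture.reference
        p1, p3 = tx.cds_to_genomic(838), tx.cds_to_genomic(840)
        calls = [
            snv(p1, ref.base(p1), "T", contig=tx.contig),
            snv(p3, ref.base(p3), "C", contig=tx.contig),
        ]
        # inner gap is 1, so max_gap=0 would normally split them ...
        assert cluster_candidates(calls, max_gap=0) == []
        # ... but same-codon membership links them when transcripts are given
        clusters = cluster_candidates(calls, max_gap=0, transcripts=[tx])
        assert len(clusters) == 1

    def test_unsorted_input_rejected(self):
        with pytest.raises(OrderingError):
            cluster_candidates([snv(200), snv(100)])

    def test_negative_max_gap_rejected(self):
        with pytest.raises(InputError):
            cluster_candidates([], max_gap=-1)

    @pytest.mark.parametrize("max_gap", [0, 1, 2])
    def test_matches_brute_force_transitive_closure(self, max_gap):
        """Seeded random sites cluster identically to an explicit
        transitive-closure oracle over pairwise inner gaps."""
        rng = np.random.default_rng(1234 + max_gap)
        positions = sorted(set(rng.integers(1, 400, size=100).tolist()))
        calls = [snv(int(p)) for p in positions]

        # oracle: union-find over all pairs with inner gap <= max_gap
        parent = list(range(len(calls)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(len(calls)), 2):
            if abs(calls[i].position - calls[j].position) - 1 <= max_gap:
                parent[find(i)] = find(j)
        groups: dict[int, list[int]] = {}
        for i in range(len(calls)):
            groups.setdefault(find(i), []).append(i)
        expected = sorted(
            tuple(calls[i].position for i in g)
            for g in groups.values()
            if len(g) >= 2
        )

        observed = sorted(
            tuple(m.position for m in c.members)
            for c in cluster_candidates(calls, max_gap=max_gap)
        )
        assert observed == expected


counts = st.integers(min_value=0, max_value=60)


class TestClassifyPhase:
    def test_hom_hom_is_assumed_cis_regardless_of_evidence(self):
        ev = PhaseEvidence(n_both_alt=0, n_alt_ref=50, n_ref_alt=50)
        assert classify_phase(ev, ("hom_alt", "hom_alt")) == "assumed_cis_homozygous"

    def test_unanimous_cis_evidence(self):
        ev = PhaseEvidence(n_both_alt=30)
        assert classify_phase(ev, ("het", "het")) == "cis"

    def test_no_informative_templates_is_unphased(self):
        assert classify_phase(PhaseEvidence(), ("het", "het")) == "unphased_no_reads"
        assert (
            classify_phase(PhaseEvidence(n_both_ref=40), ("het", "het"))
            == "unphased_no_reads"
        )

    def test_threshold_validation(self):
        with pytest.raises(InputError):
            classify_phase(PhaseEvidence(), ("het", "het"), min_support=0)
        with pytest.raises(InputError):
            classify_phase(PhaseEvidence(), ("het", "het"), max_conflict_fraction=0.5)

    @settings(max_examples=300, derandomize=True)
    @given(both=counts, ar=counts, ra=counts, bref=counts, other=counts)
    def test_matches_direct_inequality_oracle(self, both, ar, ra, bref, other):
        ev = PhaseEvidence(both, ar, ra, bref, other)
        got = classify_phase(ev, ("het", "het"), min_support=3,
                             max_conflict_fraction=0.1)
        informative = both + ar + ra
        mixed = ar + ra
        if informative == 0:
            expect = "unphased_no_reads"
        elif both >= 3 and mixed / informative <= 0.1:
            expect = "cis"
        elif mixed >= 3 and both / informative <= 0.1:
            expect = "trans"
        else:
            expect = "ambiguous"
        assert got == expect

    @settings(max_examples=200, derandomize=True)
    @given(both=counts, ar=counts, ra=counts, bref=counts, other=counts)
    def test_symmetric_under_site_swap(self, both, ar, ra, bref, other):
        ev = PhaseEvidence(both, ar, ra, bref, other)
        for gts in [("het", "het"), ("het", "hom_alt"), ("hom_alt", "hom_alt")]:
            assert classify_phase(ev, gts) == classify_phase(
                ev.swapped(), (gts[1], gts[0])
            )


class TestCollectPhaseEvidence:
    def test_homozygous_fixture_all_templates_both_alt(self, table1_bundle):
        """Planted homozygous MNV: every spanning template carries both
        alternate alleles, none carries reference."""
        fixture, paths = table1_bundle
        mnv = fixture.truth.mnvs[0]
        a, b = mnv.members[0], mnv.members[-1]
        ev = collect_phase_evidence(paths["bam"], a, b)
        with pysam.AlignmentFile(str(paths["bam"])) as bam:
            spanning = {
                r.query_name
                for r in bam.fetch(a.contig, a.position - 1, b.position)
                if r.reference_start + 1 <= a.position
                and r.reference_end >= b.position
            }
        assert ev.n_both_alt == len(spanning) > 0
        assert (ev.n_alt_ref, ev.n_ref_alt, ev.n_both_ref, ev.n_other) == (0, 0, 0, 0)

    def test_het_counts_match_simulator_truth_tally(self, table3_bundle):
        """Heterozygous cis fixture: evidence counts equal a direct tally of
        spanning templates by their haplotype of origin (recorded by the
        simulator in the read names)."""
        fixture, paths = table3_bundle
        for mnv in fixture.truth.mnvs:
            a, b = mnv.members[0], mnv.members[-1]
            ev = collect_phase_evidence(paths["bam"], a, b)
            h0 = h1 = 0
            with pysam.AlignmentFile(str(paths["bam"])) as bam:
                for r in bam.fetch(a.contig, a.position - 1, b.position):
                    if r.reference_start + 1 <= a.position and r.reference_end >= b.position:
                        if r.query_name.endswith(".h1"):
                            h1 += 1
                        else:
                            h0 += 1
            # cis truth: alt haplotype is h1, reference haplotype is h0
            assert (ev.n_both_alt, ev.n_both_ref) == (h1, h0)
            assert ev.n_alt_ref == ev.n_ref_alt == ev.n_other == 0

    def test_no_spanning_template_yields_all_zero(self, table1_bundle):
        fixture, paths = table1_bundle
        far_a = snv(10, contig=fixture.reference.contig_name)
        far_b = snv(len(fixture.reference) - 10, contig=fixture.reference.contig_name)
        ev = collect_phase_evidence(paths["bam"], far_a, far_b)
        assert ev.n_informative == 0 and ev.n_both_ref == 0
        assert classify_phase(ev, ("het", "het")) == "unphased_no_reads"

    def test_unindexed_source_rejected(self, table1_bundle, tmp_path):
        fixture, paths = table1_bundle
        sam = tmp_path / "noindex.sam"
        with pysam.AlignmentFile(str(paths["bam"])) as bam:
            with pysam.AlignmentFile(str(sam), "w", template=bam) as out:
                for r in bam.fetch():
                    out.write(r)
        a, b = fixture.truth.snvs[0], fixture.truth.snvs[1]
        with pytest.raises((InputError, ValueError)):
            collect_phase_evidence(sam, a, b)


class TestMergeCluster:
    def make_cluster(self, status="cis"):
        # CTG background, edits at first and third codon base -> TTC
        members = [snv(11, "C", "T"), snv(13, "G", "C")]
        return Cluster(members=members, phase_status=status)

    @pytest.fixture
    def reference(self):
        return ReferenceSequence("c1", "AAAAAAAAAACTGAAAAAAATCAAA")

    def test_nonconsecutive_pair_keeps_middle_base(self, reference):
        mnv = merge_cluster(self.make_cluster(), reference)
        assert (mnv.start, mnv.end) == (11, 13)
        assert (mnv.ref_allele, mnv.alt_allele) == ("CTG", "TTC")

    def test_adjacent_pair_spans_two_bases(self, reference):
        cluster = Cluster(
            members=[snv(21, "T", "A"), snv(22, "C", "G")], phase_status="cis"
        )
        mnv = merge_cluster(cluster, reference)
        assert (mnv.ref_allele, mnv.alt_allele) == ("TC", "AG")

    @pytest.mark.parametrize("status", ["trans", "ambiguous", "unphased_no_reads"])
    def test_non_cis_cluster_refused(self, reference, status):
        with pytest.raises(MergeRefusedError):
            merge_cluster(self.make_cluster(status), reference)

    def test_merged_allele_equals_sequential_substitution(self, reference):
        """Applying the merged allele reproduces the sequence obtained by
        applying each member SNV independently."""
        rng = np.random.default_rng(42)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        ref = ReferenceSequence("c1", seq)
        for _ in range(50):
            positions = sorted(rng.choice(np.arange(5, 55), size=3, replace=False))
            if positions[-1] - positions[0] > 10:
                continue
            members = []
            for p in positions:
                rb = ref.base(int(p))
                ab = "ACGT"[("ACGT".index(rb) + 1) % 4]
                members.append(snv(int(p), rb, ab))
            cluster = Cluster(members=members, phase_status="cis")
            mnv = merge_cluster(cluster, ref)
            via_merge = list(seq)
            via_merge[mnv.start - 1 : mnv.end] = list(mnv.alt_allele)
            via_snvs = list(seq)
            for m in members:
                via_snvs[m.position - 1] = m.alt_base
            assert via_merge == via_snvs
            assert len(mnv.ref_allele) == len(mnv.alt_allele)

    def test_mnv_record_invariants_enforced(self):
        from mnvrescue.mnvmerge import MnvRecord

        with pytest.raises(InputError):  # unequal allele lengths
            MnvRecord("c1", 1, 3, "ACG", "AC", [], "cis")
        with pytest.raises(InputError):  # single difference is not an MNV
            MnvRecord("c1", 1, 3, "ACG", "ACT", [], "cis")


class TestEmitVcf:
    def test_table1_components_replaced_by_delins(self, table1_bundle, tmp_path):
        fixture, paths = table1_bundle
        ref = fixture.reference
        out = tmp_path / "merged.vcf"
        emit_vcf(paths["vcf"], fixture.truth.mnvs, out)
        with pysam.VariantFile(str(out)) as vcf:
            recs = list(vcf)
        assert len(recs) == 5
        assert all(len(r.ref) >= 2 and len(r.ref) == len(r.alts[0]) for r in recs)
        positions = [r.pos for r in recs]
        assert positions == sorted(positions)

    def test_round_trip_reproduces_mnv_fields(self, table1_bundle, tmp_path):
        fixture, paths = table1_bundle
        out = tmp_path / "merged.vcf"
        emit_vcf(paths["vcf"], fixture.truth.mnvs, out)
        by_start = {m.start: m for m in fixture.truth.mnvs}
        with pysam.VariantFile(str(out)) as vcf:
            for rec in vcf:
                mnv = by_start[rec.pos]
                assert rec.ref == mnv.ref_allele
                assert rec.alts[0] == mnv.alt_allele
                assert rec.stop == mnv.end
                assert rec.info["MNV_PHASE"] == mnv.phase_status
                members = tuple(
                    f"{m.position}{m.ref_base}>{m.alt_base}" for m in mnv.members
                )
                assert tuple(rec.info["MNV_MEMBERS"]) == members

    def test_empty_merge_list_passes_everything_through(self, table1_bundle, tmp_path):
        fixture, paths = table1_bundle
        out = tmp_path / "same.vcf"
        emit_vcf(paths["vcf"], [], out)
        assert load_snv_calls(out) == load_snv_calls(paths["vcf"])

    def test_foreign_member_is_consistency_error(self, table1_bundle, tmp_path):
        from mnvrescue.errors import ConsistencyError
        from mnvrescue.mnvmerge import MnvRecord

        fixture, paths = table1_bundle
        contig = fixture.reference.contig_name
        bogus = MnvRecord(
            contig=contig, start=5, end=6, ref_allele="AA", alt_allele="CC",
            members=[snv(5, "A", "C", contig=contig), snv(6, "A", "C", contig=contig)],
            phase_status="cis",
        )
        with pytest.raises(ConsistencyError):
            emit_vcf(paths["vcf"], [bogus], tmp_path / "x.vcf")
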