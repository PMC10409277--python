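"""Read mapping, base composition and polymorphic-site extraction."""

from __future__ import annotations

import numpy as np
import pytest

from numtscan import homology, pileup, simulate
from numtscan._sequtil import random_sequence

from conftest import HET_SITES, NUMT_SITES


class TestMapReadsLightweight:
    def test_error_free_reads_map_at_truth(self, rng):
        ref = random_sequence(rng, 3_000)
        reads = [(f"r{i}", ref[s : s + 150])
                 for i, s in enumerate(rng.integers(0, 2_850, size=200))]
        alns = {a.read_id: a for a in pileup.map_reads_lightweight(reads, ref)}
        starts = {f"r{i}": int(s) + 1
                  for i, s in enumerate(rng.integers(0, 0, size=0))}
        for (rid, seq), a in zip(reads, alns.values()):
            assert a.mapped
            assert ref[a.pos - 1 : a.pos - 1 + 150] == seq

    def test_one_percent_error_reads_map_near_truth(self, genome_system,
                                                    line_a_alignments,
                                                    read_truth):
        """>=99% of uniquely placeable mtDNA-origin reads land within +-2 bp
        of truth (reads inside the planted repeat are legitimately ambiguous
        and excluded)."""
        from conftest import REPEAT_COGNATE, REPEAT_COPY_AT

        rep_len = REPEAT_COGNATE[1] - REPEAT_COGNATE[0]
        ambiguous = (
            (REPEAT_COGNATE[0] - 150, REPEAT_COGNATE[1]),
            (REPEAT_COPY_AT - 150, REPEAT_COPY_AT + rep_len),
        )
        near = total = 0
        for a in line_a_alignments:
            host, start, _ = read_truth[a.read_id]
            if host != "mt":
                continue
            if any(lo <= start <= hi for lo, hi in ambiguous):
                continue
            total += 1
            near += a.mapped and abs(a.pos - start) <= 2
        assert total > 10_000
        assert near / total >= 0.99

    def test_unrelated_read_is_unmapped(self, rng):
        ref = random_sequence(rng, 2_000)
        alien = random_sequence(rng, 150)
        (a,) = pileup.map_reads_lightweight([("x", alien)], ref)
        assert not a.mapped

    def test_read_longer_than_reference_rejected(self, rng):
        with pytest.raises(ValueError):
            pileup.map_reads_lightweight([("x", "A" * 300)],
                                         random_sequence(rng, 100))


class TestBaseComposition:
    def test_uniform_reads_give_reference_only_counts(self, rng):
        ref = random_sequence(rng, 400)
        alns = [
            pileup.Alignment(f"r{i}", 101, "+", (("M", 150),),
                             ref[100:250], 0)
            for i in range(100)
        ]
        table = pileup.base_composition(alns, ref)
        site = table.site(150)
        assert site.counts[ref[149]] == 100
        assert sum(site.counts.values()) == site.depth == 100

    def test_constructed_970_30_pileup(self, rng):
        """A site covered by 970 ref reads and 30 alt reads records alt=30 at
        depth 1000."""
        ref = random_sequence(rng, 300)
        pos = 150
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref[pos - 1]]
        alt_seq = ref[100:149] + alt + ref[150:250]
        alns = [
            pileup.Alignment(f"ref{i}", 101, "+", (("M", 150),), ref[100:250], 0)
            for i in range(970)
        ] + [
            pileup.Alignment(f"alt{i}", 101, "+", (("M", 150),), alt_seq, 1)
            for i in range(30)
        ]
        site = pileup.base_composition(alns, ref).site(pos)
        assert site.depth == 1_000
        assert site.counts[alt] == 30
        assert site.counts[ref[pos - 1]] == 970

    def test_indel_evidence_counted_at_anchor_and_deleted_positions(self, rng):
        ref = random_sequence(rng, 200)
        # read with a 2-bp deletion of ref positions 61-62 and an insertion
        # anchored after ref position 100
        seq = ref[10:60] + ref[62:100] + "GG" + ref[100:110]
        cigar = (("M", 50), ("D", 2), ("M", 38), ("I", 2), ("M", 10))
        table = pileup.base_composition(
            [pileup.Alignment("r", 11, "+", cigar, seq, 4)], ref
        )
        assert table.deletions[60] == 1 and table.deletions[61] == 1
        assert table.insertions[99] == 1
        assert table.site(61).depth == 1  # deletion evidence counts as depth

    def test_sam_with_wrong_reference_length_rejected(self, rng, tmp_path):
        ref = random_sequence(rng, 500)
        sam = tmp_path / "x.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:mt\tLN:999\n"
            "r1\t0\tmt\t10\t60\t20M\t*\t0\t0\t" + ref[9:29] + "\t*\n"
        )
        with pytest.raises(ValueError, match="length"):
            pileup.base_composition(str(sam), ref)

    def test_sam_round_trip_matches_internal_counts(self, rng, tmp_path):
        ref = random_sequence(rng, 400)
        sam = tmp_path / "x.sam"
        lines = ["@HD\tVN:1.6", f"@SQ\tSN:mt\tLN:{len(ref)}"]
        for i in range(50):
            s = 50 + i
            lines.append(
                f"r{i}\t0\tmt\t{s + 1}\t60\t100M\t*\t0\t0\t{ref[s:s+100]}\t*"
            )
        sam.write_text("\n".join(lines) + "\n")
        table = pileup.base_composition(str(sam), ref, ref_name="mt")
        assert table.n_used == 50
        assert int(table.depth[99]) == 50


class TestCallSites:
    @staticmethod
    def _table(ref, pos, alt, alt_count, depth):
        L = len(ref)
        counts = np.zeros((L, 4), dtype=np.int64)
        codes = {"A": 0, "C": 1, "G": 2, "T": 3}
        counts[:, 0] = 0
        for i, b in enumerate(ref):
            counts[i, codes[b]] = depth
        counts[pos - 1, codes[ref[pos - 1]]] = depth - alt_count
        counts[pos - 1, codes[alt]] = alt_count
        return pileup.PileupTable(
            reference=ref, base_counts=counts,
            insertions=np.zeros(L, np.int64), deletions=np.zeros(L, np.int64),
        )

    def test_both_thresholds_pass(self, rng):
        ref = random_sequence(rng, 50)
        table = self._table(ref, 25, "A" if ref[24] != "A" else "C", 15, 1_000)
        sites = pileup.call_intraindividual_sites(table)
        assert [s.pos for s in sites] == [25]
        assert sites[0].alleles[0].fraction == pytest.approx(0.015)

    @pytest.mark.parametrize("alt_count,depth", [(9, 1_000), (4, 400)])
    def test_threshold_boundaries_not_called(self, rng, alt_count, depth):
        """0.9% at depth 1000 fails the fraction floor; 1.0% with 4 reads
        fails the ~10-read floor."""
        ref = random_sequence(rng, 50)
        table = self._table(ref, 25, "A" if ref[24] != "A" else "C",
                            alt_count, depth)
        assert pileup.call_intraindividual_sites(table) == []

    def test_numt_divergent_sites_called_near_two_percent(self, line_a_sites):
        """End to end: the 12 numt-divergent sites are called from line A
        reads with variant fractions near 1/(r+1) ~= 2%."""
        called = {s.pos: s for s in line_a_sites}
        for pos in NUMT_SITES:
            assert pos in called, f"numt site {pos} not called"
            frac = called[pos].max_fraction
            assert 0.01 <= frac <= 0.045

    def test_heteroplasmic_sites_called_near_five_percent(self, line_a_sites):
        called = {s.pos: s for s in line_a_sites}
        for pos in HET_SITES:
            assert pos in called, f"heteroplasmic site {pos} not called"
            assert called[pos].max_fraction == pytest.approx(0.05, abs=0.02)

    def test_no_spurious_calls_on_clean_compartment(self, line_a_sites):
        """At default thresholds nothing is called outside the planted
        polymorphic positions (sequencing error alone never reaches 1% and
        10 reads at ~1,200x depth)."""
        expected = set(NUMT_SITES) | set(HET_SITES)
        unexpected = [s.pos for s in line_a_sites if s.pos not in expected]
        assert unexpected == []


class TestRestrictAndShare:
    def test_restriction_follows_partition_lookup(self, rng):
        labels = np.full(100, 2, np.int8)
        labels[39:60] = 4
        part = homology.CategoryPartition(labels=labels)
        sites = [
            pileup.PolymorphicSite(pos=p, ref="A", alleles=(
                pileup.VariantAllele("C", 20, 0.02, "SNP"),))
            for p in (10, 45, 70)
        ]
        kept = pileup.restrict_to_category(sites, part, categories={2})
        assert [s.pos for s in kept] == [10, 70]
        # brute-force oracle over random partitions and positions
        rlab = np.asarray(rng.integers(1, 9, size=200), dtype=np.int8)
        rpart = homology.CategoryPartition(labels=rlab)
        rsites = [
            pileup.PolymorphicSite(pos=int(p), ref="A", alleles=(
                pileup.VariantAllele("C", 20, 0.02, "SNP"),))
            for p in rng.integers(1, 201, size=50)
        ]
        cats = {2, 4}
        kept = pileup.restrict_to_category(rsites, rpart, categories=cats)
        expected = [s for s in rsites if rlab[s.pos - 1] in cats]
        assert kept == expected

    def test_all_category2_is_identity(self):
        part = homology.CategoryPartition(labels=np.full(50, 2, np.int8))
        sites = [
            pileup.PolymorphicSite(pos=p, ref="A", alleles=(
                pileup.VariantAllele("C", 20, 0.02, "SNP"),))
            for p in (3, 30)
        ]
        assert pileup.restrict_to_category(sites, part) == sites

    def test_shared_sites_intersection(self):
        def mk(pos, alt):
            return pileup.PolymorphicSite(pos=pos, ref="A", alleles=(
                pileup.VariantAllele(alt, 20, 0.02, "SNP"),))

        a = [mk(10, "C"), mk(20, "G"), mk(30, "T")]
        b = [mk(20, "G"), mk(30, "C"), mk(40, "C")]
        assert pileup.shared_sites([], b) == []
        assert pileup.shared_sites(a, b) == [20, 30]
        assert pileup.shared_sites(a, b, by_allele=True) == [20]

    def test_shared_sites_matches_set_oracle(self, rng):
        def mk(pos):
            return pileup.PolymorphicSite(pos=int(pos), ref="A", alleles=(
                pileup.VariantAllele("C", 20, 0.02, "SNP"),))

        pa = rng.choice(500, size=60, replace=False)
        pb = rng.choice(500, size=60, replace=False)
        a, b = [mk(p) for p in pa], [mk(p) for p in pb]
        assert pileup.shared_sites(a, b) == sorted(set(pa) & set(pb))


class TestReferenceDependency:
    """The central result: whether numt-divergent sites survive category-2
    restriction depends entirely on which nuclear reference built the
    partition."""

    def test_numt_bearing_reference_removes_all_numt_sites(
        self, line_a_sites, partition_vs_line_a
    ):
        kept = pileup.restrict_to_category(line_a_sites, partition_vs_line_a)
        kept_pos = {s.pos for s in kept}
        assert not kept_pos & set(NUMT_SITES)

    def test_numt_lacking_reference_removes_none(
        self, line_a_sites, partition_vs_line_b
    ):
        kept = pileup.restrict_to_category(line_a_sites, partition_vs_line_b)
        kept_pos = {s.pos for s in kept}
        assert set(NUMT_SITES) <= kept_pos

    def test_true_heteroplasmy_survives_both_references(
        self, line_a_sites, partition_vs_line_a, partition_vs_line_b
    ):
        for part in (partition_vs_line_a, partition_vs_line_b):
            kept = {s.pos for s in pileup.restrict_to_category(line_a_sites, part)}
            assert set(HET_SITES) <= kept
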