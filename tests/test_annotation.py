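"""Annotation harmonization: loading, consolidation, placement, merging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from miratlas import annotation as ann
from miratlas import simulate as sim
from miratlas.errors import DataError, ParseError, ValidationError

from conftest import brute_force_clusters, naive_exact_scan


# ---------------------------------------------------------------------------
# loading and normalization
# ---------------------------------------------------------------------------

class TestLoadMatureFasta:
    def test_normalizes_rna_to_uppercase_dna(self, tmp_path):
        f = tmp_path / "m.fa"
        f.write_text(">m1\nugagguaguagguuguauagu\n")
        recs = ann.load_mature_fasta(f, "cfa")
        assert recs == [
            ann.MatureSequence("m1", "cfa", "TGAGGTAGTAGGTTGTATAGT")
        ]

    def test_empty_file_gives_empty_collection(self, tmp_path):
        f = tmp_path / "empty.fa"
        f.write_text("")
        assert ann.load_mature_fasta(f, "cfa") == []

    def test_duplicate_names_rejected(self, tmp_path):
        f = tmp_path / "dup.fa"
        f.write_text(">m1\nACGTACGTACGTACGTA\n>m1\nTTTTACGTACGTACGTA\n")
        with pytest.raises(ValidationError, match="duplicate"):
            ann.load_mature_fasta(f, "cfa")

    @pytest.mark.parametrize("seq", ["ACGTXCGTACGTACGTA", "ACGT", "A" * 31])
    def test_invalid_sequences_rejected(self, tmp_path, seq):
        f = tmp_path / "bad.fa"
        f.write_text(f">m1\n{seq}\n")
        with pytest.raises(ValidationError):
            ann.load_mature_fasta(f, "cfa")

    def test_non_fasta_text_is_parse_error(self, tmp_path):
        f = tmp_path / "bad.txt"
        f.write_text("this is not fasta\n")
        with pytest.raises(ParseError):
            ann.load_mature_fasta(f, "cfa")


# ---------------------------------------------------------------------------
# consolidation
# ---------------------------------------------------------------------------

SEQ17 = "ACGTACGTACGTACGTA"
SEQ18 = "TTGCATGCATGCATGCAT"


def _ms(name, sp, seq):
    return ann.MatureSequence(name, sp, seq)


class TestConsolidate:
    def test_fully_conserved_collapses_to_one(self):
        sets = {
            "cfa": [_ms("cfa-m1", "cfa", SEQ17)],
            "rno": [_ms("rno-m1", "rno", SEQ17)],
            "hsa": [_ms("hsa-m1", "hsa", SEQ17)],
        }
        out = ann.consolidate_sequences(sets, precedence=["cfa", "rno", "hsa"])
        assert len(out) == 1
        assert len(out[0].members) == 3
        assert out[0].representative_name == "cfa-m1"

    def test_partial_sharing_merges_by_sequence(self):
        sets = {
            "cfa": [_ms("d1", "cfa", SEQ17), _ms("d2", "cfa", SEQ18)],
            "rno": [_ms("r1", "rno", SEQ18)],
        }
        out = ann.consolidate_sequences(sets)
        assert len(out) == 2
        shared = next(c for c in out if c.sequence == SEQ18)
        assert {sp for _, sp in shared.members} == {"cfa", "rno"}

    def test_pairwise_distinct_sequences_stay_separate(self):
        seqs = ["A" * 8 + "C" * 9, "G" * 8 + "T" * 9, "AC" * 9, "GT" * 9,
                "AG" * 9, "CT" * 9]
        sets = {
            "cfa": [_ms("d1", "cfa", seqs[0]), _ms("d2", "cfa", seqs[1])],
            "rno": [_ms("r1", "rno", seqs[2]), _ms("r2", "rno", seqs[3])],
            "hsa": [_ms("h1", "hsa", seqs[4]), _ms("h2", "hsa", seqs[5])],
        }
        assert len(ann.consolidate_sequences(sets)) == 6

    @given(st.permutations(["cfa", "rno", "hsa"]))
    @settings(max_examples=6, deadline=None)
    def test_order_independent_and_idempotent(self, order):
        base = {
            "cfa": [_ms("d1", "cfa", SEQ17), _ms("d2", "cfa", SEQ18)],
            "rno": [_ms("r1", "rno", SEQ17)],
            "hsa": [_ms("h1", "hsa", SEQ18)],
        }
        ref = ann.consolidate_sequences(base, precedence=["cfa", "rno", "hsa"])
        shuffled = {sp: base[sp] for sp in order}
        out = ann.consolidate_sequences(shuffled, precedence=["cfa", "rno", "hsa"])
        assert out == ref
        # idempotent: consolidating the members again changes nothing
        assert len(out) == len({c.sequence for c in out})

    def test_total_distinct_sequences_preserved(self):
        rng = np.random.default_rng(5)
        sets = {}
        all_seqs = set()
        for sp in ("cfa", "rno"):
            recs = []
            for i in range(20):
                s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 20)])
                recs.append(_ms(f"{sp}-m{i}", sp, s))
                all_seqs.add(s)
            sets[sp] = recs
        out = ann.consolidate_sequences(sets)
        assert {c.sequence for c in out} == all_seqs


# ---------------------------------------------------------------------------
# exact placement
# ---------------------------------------------------------------------------

class TestAlignExact:
    def _cs(self, seq):
        return ann.ConsolidatedSequence(seq, frozenset([("m", "cfa")]), "m")

    def test_single_forward_hit(self):
        pat = "AAACCCGGGTTTACACA"
        genome = {"chr1": "TT" + pat + "TTT"}
        hits, rep = ann.align_exact([self._cs(pat)], genome)
        assert [(h.chrom, h.start, h.end, h.strand) for h in hits] == [
            ("chr1", 2, 2 + len(pat), "+")
        ]
        assert rep.n_aligned == 1

    def test_reverse_strand_hit_is_reverse_complement(self):
        pat = "AACCGGTTACGTACGTA"
        genome = {"chr1": "GG" + ann.reverse_complement(pat) + "AA"}
        hits, _ = ann.align_exact([self._cs(pat)], genome)
        assert len(hits) == 1 and hits[0].strand == "-"

    def test_two_hits_retained_within_threshold(self):
        pat = "AAACCCGGGTTTACACA"
        genome = {"chr1": pat + "TTTTT" + pat}
        hits, rep = ann.align_exact([self._cs(pat)], genome)
        assert len(hits) == 2 and not rep.excluded_multi

    def test_eleven_placements_excluded_strict_boundary(self):
        pat = "ACGTTGCAACGTTGCAT"
        genome = {"chr1": ("TTTTT" + pat) * 11}
        hits, rep = ann.align_exact([self._cs(pat)], genome)
        assert hits == []
        assert rep.excluded_multi[pat] == 11
        hits10, rep10 = ann.align_exact(
            [self._cs(pat)], {"chr1": ("TTTTT" + pat) * 10}
        )
        assert len(hits10) == 10 and not rep10.excluded_multi

    def test_n_in_genome_never_matches(self):
        pat = "AAACCCGGGTTTACACA"
        genome = {"chr1": pat.replace("A", "N", 1) + "TTT"}
        hits, rep = ann.align_exact([self._cs(pat)], genome)
        assert hits == [] and rep.unaligned == [pat]

    def test_agrees_with_sliding_window_oracle(self):
        rng = np.random.default_rng(7)
        genome = {"chr1": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5000)]),
                  "chr2": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3000)])}
        patterns = []
        for i in range(30):
            L = int(rng.integers(15, 26))
            if i % 3 == 0:  # planted: guaranteed hits
                start = int(rng.integers(0, 5000 - L))
                patterns.append(genome["chr1"][start: start + L])
            else:
                patterns.append(
                    "".join(np.array(list("ACGT"))[rng.integers(0, 4, L)])
                )
        patterns = list(dict.fromkeys(patterns))
        css = [self._cs(p) for p in patterns]
        hits, rep = ann.align_exact(css, genome, max_locations=10**9)
        got = {}
        for h in hits:
            got.setdefault(h.sequence_ref, set()).add(
                (h.chrom, h.start, h.end, h.strand)
            )
        oracle = naive_exact_scan(patterns, genome)
        for p in patterns:
            assert got.get(p, set()) == set(oracle[p]), p


# ---------------------------------------------------------------------------
# locus merging
# ---------------------------------------------------------------------------

def _hits_and_catalog(intervals):
    """Build GenomeHits + consolidated catalog from (chrom,start,end,strand)."""
    rng = np.random.default_rng(99)
    cons = {}
    hits = []
    for k, (chrom, s, e, strand) in enumerate(intervals):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, e - s)])
        while seq in cons:
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, e - s)])
        cons[seq] = ann.ConsolidatedSequence(
            seq, frozenset([(f"m{k}", "cfa")]), f"m{k}"
        )
        hits.append(ann.GenomeHit(seq, chrom, s, e, strand))
    return hits, cons


class TestMergeLoci:
    def test_overlapping_hits_merge_to_spanning_locus(self):
        hits, cons = _hits_and_catalog(
            [("chr1", 10, 32, "+"), ("chr1", 12, 34, "+")]
        )
        aset = ann.merge_loci(hits, cons)
        assert len(aset) == 1
        loc = aset.loci[0]
        assert (loc.start, loc.end, loc.strand) == (10, 34, "+")

    def test_strands_never_merge(self):
        hits, cons = _hits_and_catalog(
            [("chr1", 10, 32, "+"), ("chr1", 10, 32, "-")]
        )
        assert len(ann.merge_loci(hits, cons)) == 2

    def test_distant_hits_stay_separate(self):
        hits, cons = _hits_and_catalog(
            [("chr1", 10, 32, "+"), ("chr1", 200, 222, "+")]
        )
        assert len(ann.merge_loci(hits, cons)) == 2

    def test_touching_hits_separate_at_zero_tolerance(self):
        hits, cons = _hits_and_catalog(
            [("chr1", 10, 30, "+"), ("chr1", 30, 50, "+")]
        )
        assert len(ann.merge_loci(hits, cons, gap_tolerance=0)) == 2
        assert len(ann.merge_loci(hits, cons, gap_tolerance=1)) == 1

    @pytest.mark.parametrize("gap_tolerance", [0, 5])
    def test_equals_brute_force_transitive_clustering(self, gap_tolerance):
        rng = np.random.default_rng(13)
        intervals = []
        for _ in range(300):
            chrom = f"chr{rng.integers(1, 3)}"
            start = int(rng.integers(0, 2000))
            intervals.append(
                (chrom, start, start + int(rng.integers(16, 26)),
                 "+" if rng.random() < 0.5 else "-")
            )
        hits, cons = _hits_and_catalog(intervals)
        aset = ann.merge_loci(hits, cons, gap_tolerance=gap_tolerance)
        expected = brute_force_clusters(intervals, gap_tolerance)
        got = set()
        seq_to_idx = {h.sequence_ref: i for i, h in enumerate(hits)}
        for loc in aset.loci:
            got.add(frozenset(seq_to_idx[s] for s in loc.member_sequences))
        assert got == expected

    def test_merged_loci_nonoverlapping_per_strand(self):
        rng = np.random.default_rng(23)
        intervals = [
            ("chr1", int(s), int(s) + 20, "+")
            for s in rng.integers(0, 500, 100)
        ]
        hits, cons = _hits_and_catalog(intervals)
        aset = ann.merge_loci(hits, cons)
        locs = sorted(aset.loci, key=lambda l: l.start)
        for a, b in zip(locs, locs[1:]):
            assert a.end <= b.start

    def test_name_collision_disambiguated(self):
        seq1, seq2 = "ACGTACGTACGTACGTA", "TGCATGCATGCATGCAT"
        cons = {
            s: ann.ConsolidatedSequence(s, frozenset([("mir-9", "cfa")]), "mir-9")
            if i == 0 else
            ann.ConsolidatedSequence(s, frozenset([("mir-9", "rno")]), "mir-9")
            for i, s in enumerate([seq1, seq2])
        }
        hits = [
            ann.GenomeHit(seq1, "chr1", 0, 17, "+"),
            ann.GenomeHit(seq2, "chr1", 100, 117, "+"),
        ]
        aset = ann.merge_loci(hits, cons)
        assert sorted(l.name for l in aset.loci) == ["mir-9-loc1", "mir-9-loc2"]


# ---------------------------------------------------------------------------
# composition, round trips
# ---------------------------------------------------------------------------

class TestBuildAnnotation:
    @pytest.fixture(scope="class")
    def built(self, tmp_path_factory):
        td = tmp_path_factory.mktemp("ann")
        cfg = sim.SimulationConfig(seed=29, n_loci=50, n_te=5, n_hte=5,
                                   n_reference=2)
        genome, truth, species_sets = sim.gen_genome_and_annotation(cfg)
        sim.write_fasta(genome, td / "genome.fa")
        for sp, seqs in species_sets.items():
            sim.write_fasta(seqs, td / f"{sp}.fa")
        hcfg = ann.HarmonizerConfig(
            species_fastas={sp: td / f"{sp}.fa" for sp in cfg.species},
            genome_fasta=td / "genome.fa", target_species="cfa",
        )
        return ann.build_annotation(hcfg), truth

    def test_recovers_planted_loci_exactly(self, built):
        (aset, _), truth = built
        planted = {(l.chrom, l.start, l.end, l.strand, l.name)
                   for l in truth.loci}
        got = {(l.chrom, l.start, l.end, l.strand, l.name) for l in aset.loci}
        assert got == planted

    def test_funnel_counts_consistent(self, built):
        (aset, funnel), truth = built
        assert funnel["n_loci"] == len(aset) == 50
        assert funnel["n_excluded_multi"] == 1  # the planted multi-mapper
        assert funnel["n_aligned"] == 50
        assert funnel["n_consolidated"] == 51
        assert funnel["n_input_sequences"] == sum(
            len(v) for v in truth.species_membership.values()
        ) + 3  # multi-mapper present in all three catalogues

    def test_species_provenance_matches_truth(self, built):
        (aset, _), truth = built
        by_name = aset.by_name()
        for name, carriers in truth.species_membership.items():
            assert by_name[name].species_provenance == frozenset(carriers)

    def test_gff3_round_trip(self, built, tmp_path):
        (aset, _), _ = built
        path = tmp_path / "a.gff3"
        ann.write_gff3(aset, path)
        back = ann.read_gff3(path)
        assert [(l.chrom, l.start, l.end, l.strand, l.name,
                 l.species_provenance, l.member_sequences)
                for l in back.loci] == [
            (l.chrom, l.start, l.end, l.strand, l.name,
             l.species_provenance, l.member_sequences)
            for l in aset.loci
        ]

    def test_bed_is_zero_based_halfopen_gff_one_based(self, built, tmp_path):
        (aset, _), _ = built
        ann.write_bed(aset, tmp_path / "a.bed")
        ann.write_gff3(aset, tmp_path / "a.gff3")
        bed = (tmp_path / "a.bed").read_text().splitlines()[0].split("\t")
        gff = [l for l in (tmp_path / "a.gff3").read_text().splitlines()
               if not l.startswith("#")][0].split("\t")
        assert int(gff[3]) == int(bed[1]) + 1
        assert int(gff[4]) == int(bed[2])

    def test_no_genome_matches_gives_empty_set(self, tmp_path):
        (tmp_path / "g.fa").write_text(">chr1\n" + "A" * 500 + "\n")
        (tmp_path / "cfa.fa").write_text(">m1\n" + "CGTCGTCGATGCATGCA" + "\n")
        hcfg = ann.HarmonizerConfig(
            species_fastas={"cfa": tmp_path / "cfa.fa"},
            genome_fasta=tmp_path / "g.fa", target_species="cfa",
        )
        aset, funnel = ann.build_annotation(hcfg)
        assert len(aset) == 0 and funnel["n_aligned"] == 0
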