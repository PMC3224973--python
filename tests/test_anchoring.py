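"""In-silico PCR marker placement, scaffold anchoring/orientation,
pseudochromosome (AGP) construction and coverage arithmetic."""

import numpy as np
import pytest

from linkanchor import anchoring as A
from linkanchor._seq import find_all, random_sequence, revcomp
from linkanchor.anchoring import (
    AnchorAssignment,
    MarkerHit,
    align_markers,
    anchor_scaffolds,
    build_pseudochromosomes,
    coverage_stats,
    orient_scaffolds,
    read_agp,
    read_hits_bed,
    write_agp,
    write_hits_bed,
)
from linkanchor.linkage import LinkageGroup, LinkageMap
from linkanchor.simulate import Marker


def mk(id, scaffold, pos, fwd, rev, mtype="InDel"):
    return Marker(id, mtype, scaffold, pos, fwd, rev, 100, 94, "A01", 0.0)


def simple_map(loci_by_group):
    return LinkageMap(groups=[
        LinkageGroup(name=g, loci=sorted(v, key=lambda t: t[1]))
        for g, v in loci_by_group.items()
    ])


class TestFindAll:
    def test_matches_str_find_oracle(self):
        rng = np.random.default_rng(0)
        hay = random_sequence(50_000, rng)
        pats = [hay[100:120], hay[40_000:40_022], revcomp(hay[500:520]), "ACGT" * 5]
        got = find_all(hay, pats)
        for p, positions in zip(pats, got):
            expect, s = [], hay.find(p)
            while s != -1:
                expect.append(s)
                s = hay.find(p, s + 1)
            assert positions == expect

    def test_n_bases_never_match(self):
        hay = "ACGTN" * 100
        assert find_all(hay, ["ACGTNACG"[:8].replace("N", "A")]) == [[]]


class TestAlignMarkers:
    def test_synthetic_markers_hit_source_positions(self, small_map_and_hits):
        ds, _, hits = small_map_and_hits
        by_marker = {}
        for h in hits:
            by_marker.setdefault(h.marker_id, []).append(h)
        n_checked = 0
        for m in ds.markers:
            hs = by_marker.get(m.id, [])
            own = [h for h in hs if h.scaffold_id == m.scaffold_id]
            assert own, f"{m.id} missed its source scaffold"
            h = own[0]
            assert h.amplicon_start_bp <= m.scaffold_pos_bp < h.amplicon_end_bp
            n_checked += 1
        assert n_checked == len(ds.markers)

    def test_duplicated_locus_flagged_non_unique(self):
        rng = np.random.default_rng(1)
        seq = random_sequence(2_000, rng)
        m = mk("m1", "s1", 950, seq[900:920], revcomp(seq[980:1000]))
        seqs = {"s1": seq, "s2": random_sequence(500, rng) + seq[850:1050]}
        hits = align_markers([m], seqs)
        assert len(hits) == 2 and all(not h.unique for h in hits)

    def test_minus_template_orientation_detected(self):
        rng = np.random.default_rng(2)
        seq = random_sequence(1_000, rng)
        m = mk("m1", "s1", 450, seq[400:420], revcomp(seq[480:500]))
        hits = align_markers([m], {"rc": revcomp(seq)})
        assert len(hits) == 1 and hits[0].template_strand == "-"
        # same amplicon located from the other end
        assert hits[0].amplicon_end_bp - hits[0].amplicon_start_bp == 100

    def test_primer_with_n_skipped_with_warning(self):
        m = mk("m1", "s1", 0, "ACGTNACGTACGTACGTACG", "ACGTACGTACGTACGTACGT")
        with pytest.warns(UserWarning, match="non-ACGT"):
            hits = align_markers([m], {"s1": "ACGT" * 100})
        assert hits == []

    def test_hit_count_matches_naive_oracle(self):
        rng = np.random.default_rng(3)
        seqs = {f"s{i}": random_sequence(20_000, rng) for i in range(3)}
        markers = []
        for i, (sid, seq) in enumerate(seqs.items()):
            start = 5_000 + 100 * i
            markers.append(mk(f"m{i}", sid, start + 50, seq[start : start + 20],
                              revcomp(seq[start + 100 : start + 120])))
        hits = align_markers(markers, seqs)
        from test_markers import naive_amplicon_scan

        for m in markers:
            got = sum(1 for h in hits if h.marker_id == m.id)
            assert got == naive_amplicon_scan(m.primer_fwd, m.primer_rev, seqs)


class TestAnchorScaffolds:
    def test_unanimous_support_anchors(self):
        lmap = simple_map({"A09": [("m1", 0.0), ("m2", 5.0), ("m3", 12.0)]})
        hits = [MarkerHit(f"m{i}", "sc1", 100 * i, 100 * i + 90, "+") for i in (1, 2, 3)]
        out = anchor_scaffolds(lmap, hits)
        a = out[0]
        assert a.chromosome == "A09" and not a.conflict
        assert a.position_cM == 5.0  # median
        assert a.supporting_markers == ["m1", "m2", "m3"]

    def test_even_split_is_conflict(self):
        lmap = simple_map({"A01": [("m1", 0.0)], "A02": [("m2", 0.0)]})
        hits = [MarkerHit("m1", "sc1", 0, 90, "+"), MarkerHit("m2", "sc1", 500, 590, "+")]
        out = anchor_scaffolds(lmap, hits)
        assert out[0].conflict and out[0].chromosome == ""

    def test_weak_majority_below_two_thirds_is_conflict(self):
        lmap = simple_map({"A01": [("m1", 0.0), ("m2", 1.0), ("m3", 2.0)],
                           "A02": [("m4", 0.0), ("m5", 1.0)]})
        hits = [MarkerHit(m, "sc1", i * 300, i * 300 + 90, "+")
                for i, m in enumerate(["m1", "m2", "m3", "m4", "m5"])]
        out = anchor_scaffolds(lmap, hits)
        assert out[0].conflict  # 3/5 < 2/3

    def test_non_unique_hits_ignored(self):
        lmap = simple_map({"A01": [("m1", 0.0), ("m2", 3.0)]})
        hits = [MarkerHit("m1", "sc1", 0, 90, "+", unique=False),
                MarkerHit("m2", "sc1", 500, 590, "+")]
        out = anchor_scaffolds(lmap, hits)
        assert out[0].supporting_markers == ["m2"]


class TestOrientScaffolds:
    def _assign(self, markers):
        return [AnchorAssignment("sc1", "A01", 1.0, supporting_markers=markers)]

    def test_cm_increasing_with_bp_is_plus(self):
        lmap = simple_map({"A01": [("m1", 0.0), ("m2", 8.0)]})
        hits = [MarkerHit("m1", "sc1", 100, 190, "+"), MarkerHit("m2", "sc1", 5_000, 5_090, "+")]
        out = orient_scaffolds(self._assign(["m1", "m2"]), hits, lmap)
        assert out[0].orientation == "+"

    def test_cm_decreasing_with_bp_is_minus(self):
        lmap = simple_map({"A01": [("m1", 8.0), ("m2", 0.0)]})
        hits = [MarkerHit("m1", "sc1", 100, 190, "+"), MarkerHit("m2", "sc1", 5_000, 5_090, "+")]
        out = orient_scaffolds(self._assign(["m1", "m2"]), hits, lmap)
        assert out[0].orientation == "-"

    def test_same_bin_undetermined(self):
        lmap = simple_map({"A01": [("m1", 2.0), ("m2", 2.0)]})
        hits = [MarkerHit("m1", "sc1", 100, 190, "+"), MarkerHit("m2", "sc1", 5_000, 5_090, "+")]
        out = orient_scaffolds(self._assign(["m1", "m2"]), hits, lmap)
        assert out[0].orientation == "undetermined"

    def test_reversed_group_coordinates_flip_every_orientation(self, small_map_and_hits):
        """Reversing a linkage group's coordinate direction is an
        involution: every orientation flips, scaffold order reverses."""
        ds, lmap, hits = small_map_and_hits
        fwd = orient_scaffolds(anchor_scaffolds(lmap, hits), hits, lmap)
        flipped = LinkageMap(groups=[
            LinkageGroup(name=g.name,
                         loci=[(m, g.length_cM - p) for m, p in reversed(g.loci)])
            for g in lmap.groups
        ])
        rev = orient_scaffolds(anchor_scaffolds(flipped, hits), hits, flipped)
        ori_f = {a.scaffold_id: a.orientation for a in fwd if not a.conflict}
        ori_r = {a.scaffold_id: a.orientation for a in rev if not a.conflict}
        assert set(ori_f) == set(ori_r)
        for sid in ori_f:
            if ori_f[sid] in "+-":
                assert ori_r[sid] == ("-" if ori_f[sid] == "+" else "+")
        lengths = {s.id: s.length_bp for s in ds.scaffolds}
        bf = build_pseudochromosomes([a for a in fwd if not a.conflict], lengths)
        br = build_pseudochromosomes([a for a in rev if not a.conflict], lengths)
        for chrom, order_f in bf.scaffold_order().items():
            ids_f = [sid for sid, _ in order_f]
            ids_r = [sid for sid, _ in br.scaffold_order()[chrom]]
            assert ids_r == ids_f[::-1]


class TestPseudochromosomes:
    def _three(self):
        return [AnchorAssignment(f"sc{i}", "A01", float(i), "+", [f"m{i}"])
                for i in (1, 2, 3)]

    def test_object_length_with_gaps(self):
        lengths = {f"sc{i}": 1_000 for i in (1, 2, 3)}
        build = build_pseudochromosomes(self._three(), lengths, gap_bp=100)
        assert build.object_lengths() == {"A01": 3_200}

    def test_agp_round_trip(self, tmp_path):
        lengths = {f"sc{i}": 1_000 + i for i in (1, 2, 3)}
        build = build_pseudochromosomes(self._three(), lengths, gap_bp=100)
        p = tmp_path / "x.agp"
        write_agp(build, p)
        again = read_agp(p)
        assert again.components == build.components
        assert again.gap_bp == build.gap_bp

    def test_duplicate_assignment_rejected(self):
        dup = self._three() + [AnchorAssignment("sc1", "A02", 0.0, "+", ["m9"])]
        with pytest.raises(ValueError, match="assigned more than once"):
            build_pseudochromosomes(dup, {f"sc{i}": 10 for i in (1, 2, 3)})

    def test_every_scaffold_partitioned(self, small_map_and_hits):
        ds, lmap, hits = small_map_and_hits
        assignments = orient_scaffolds(anchor_scaffolds(lmap, hits), hits, lmap)
        anchored = {a.scaffold_id for a in assignments if not a.conflict and a.chromosome}
        conflicting = {a.scaffold_id for a in assignments if a.conflict}
        with_support = {a.scaffold_id for a in assignments}
        all_ids = {s.id for s in ds.scaffolds}
        assert anchored | conflicting == with_support <= all_ids
        assert not anchored & conflicting
        build = build_pseudochromosomes(
            [a for a in assignments if not a.conflict], {s.id: s.length_bp for s in ds.scaffolds})
        placed = [c.component_id for c in build.components if c.component_type == "W"]
        assert sorted(placed) == sorted(anchored)

    def test_fasta_matches_agp_coordinates(self, tmp_path):
        rng = np.random.default_rng(8)
        seqs = {f"sc{i}": random_sequence(1_000, rng) for i in (1, 2, 3)}
        asg = self._three()
        asg[1].orientation = "-"
        build = build_pseudochromosomes(asg, {k: 1_000 for k in seqs}, gap_bp=50)
        fa = tmp_path / "pseudo.fasta"
        A.write_pseudomolecule_fasta(build, seqs, fa)
        from Bio import SeqIO

        rec = next(SeqIO.parse(str(fa), "fasta"))
        full = str(rec.seq)
        assert len(full) == 3 * 1_000 + 2 * 50
        for c in build.components:
            if c.component_type == "W":
                expect = seqs[c.component_id]
                if c.orientation == "-":
                    expect = revcomp(expect)
                assert full[c.object_beg - 1 : c.object_end] == expect
            else:
                assert set(full[c.object_beg - 1 : c.object_end]) == {"N"}


class TestCoverage:
    @pytest.mark.parametrize("bp,expect", [
        (20_867_750, 7.35),
        (27_594_208, 9.72),
        (0, 0.0),
    ])
    def test_percent_of_genome(self, bp, expect):
        asg = [AnchorAssignment("sc1", "A01", 0.0, "+", ["m1"])] if bp else []
        cov = coverage_stats(asg, {"sc1": bp}, 283_800_000)
        assert cov["total_coverage_pct"] == expect

    def test_percentages_consistent_with_total(self, small_map_and_hits):
        ds, lmap, hits = small_map_and_hits
        asg = [a for a in anchor_scaffolds(lmap, hits) if not a.conflict]
        lengths = {s.id: s.length_bp for s in ds.scaffolds}
        cov = coverage_stats(asg, lengths, ds.genome.total_length_bp)
        assert cov["total_anchored_bp"] == sum(
            d["anchored_bp"] for d in cov["per_chromosome"].values())
        raw = 100 * cov["total_anchored_bp"] / ds.genome.total_length_bp
        assert cov["total_coverage_pct"] == pytest.approx(raw, abs=0.005)

    def test_bad_genome_size(self):
        with pytest.raises(ValueError):
            coverage_stats([], {}, 0)


class TestBedIO:
    def test_round_trip(self, tmp_path):
        hits = [MarkerHit("m1", "s1", 10, 110, "+", True),
                MarkerHit("m2", "s2", 5, 200, "-", False)]
        p = tmp_path / "hits.bed"
        write_hits_bed(hits, p)
        assert read_hits_bed(p) == hits
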