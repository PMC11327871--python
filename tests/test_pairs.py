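import numpy as np
import pytest

from atlaskit import (
    Annotation,
    classify_all,
    classify_pair,
    closest_partner,
)
from atlaskit.pairs import tss_distance
from atlaskit.simulate import FixtureSpec, simulate_annotations

from conftest import make_gene


def lnc(gene_id, exons, strand, chrom="chr1"):
    return make_gene(gene_id, exons, strand, chrom=chrom, biotype_class="lnc")


def pcg(gene_id, exons, strand, chrom="chr1"):
    return make_gene(gene_id, exons, strand, chrom=chrom, biotype_class="pcg")


# 12 constructed geometries: 3 orientations x {intergenic, nested-intronic,
# exonic-overlap} in both strand polarities (sense covers +/+ and -/-;
# antisense covers '-' focal left and right of the '+' partner).
TRUTH_TABLE = [
    # intergenic, sense, both polarities
    ("inter_sense_pp", lnc("l", [(1000, 1500)], "+"), pcg("p", [(3000, 4000)], "+"),
     "intergenic", "sense", "lncgSSinter"),
    ("inter_sense_mm", lnc("l", [(1000, 1500)], "-"), pcg("p", [(3000, 4000)], "-"),
     "intergenic", "sense", "lncgSSinter"),
    # intergenic, divergent: '-' gene left of '+' gene, focal either member
    ("inter_div_minus_focal", lnc("l", [(500, 900)], "-"), pcg("p", [(1000, 2000)], "+"),
     "intergenic", "divergent", "lncgDIVinter"),
    ("inter_div_plus_focal", lnc("l", [(1000, 2000)], "+"), pcg("p", [(500, 900)], "-"),
     "intergenic", "divergent", "lncgDIVinter"),
    # intergenic, convergent: '+' gene left, tails facing
    ("inter_conv_plus_focal", lnc("l", [(100, 500)], "+"), pcg("p", [(800, 1600)], "-"),
     "intergenic", "convergent", "lncgCONVinter"),
    ("inter_conv_minus_focal", lnc("l", [(800, 1600)], "-"), pcg("p", [(100, 500)], "+"),
     "intergenic", "convergent", "lncgCONVinter"),
    # genic nested in intron, sense, both polarities
    ("genic_nested_intron_pp",
     lnc("l", [(1200, 1300)], "+"), pcg("p", [(1000, 1100), (1900, 2000)], "+"),
     "genic", "sense", "lncgSSinNest"),
    ("genic_nested_intron_mm",
     lnc("l", [(1200, 1300)], "-"), pcg("p", [(1000, 1100), (1900, 2000)], "-"),
     "genic", "sense", "lncgSSinNest"),
    # genic antisense: orientation follows the same TSS-position rule as
    # intergenic pairs (a '-' TSS left of the '+' TSS cannot overlap it,
    # so overlapping antisense pairs resolve to convergent), flagged below
    ("genic_nested_antisense",
     lnc("l", [(1200, 1300)], "-"), pcg("p", [(1000, 1100), (1900, 2000)], "+"),
     "genic", "convergent", "lncgCONVinNest"),
    # genic exonic overlap, not nested, sense and both antisense variants
    ("genic_exonic_sense",
     lnc("l", [(900, 1100)], "+"), pcg("p", [(1000, 2000)], "+"),
     "genic", "sense", "lncgSSexOvlp"),
    ("genic_exonic_antisense_left",
     lnc("l", [(900, 1050)], "-"), pcg("p", [(1000, 2000)], "+"),
     "genic", "convergent", "lncgCONVexOvlp"),
    ("genic_exonic_antisense_right",
     lnc("l", [(1900, 2100)], "-"), pcg("p", [(1000, 2000)], "+"),
     "genic", "convergent", "lncgCONVexOvlp"),
]


class TestClassifyPair:
    @pytest.mark.parametrize(
        "focal,partner,category,orientation,label",
        [t[1:] for t in TRUTH_TABLE],
        ids=[t[0] for t in TRUTH_TABLE],
    )
    def test_truth_table(self, focal, partner, category, orientation, label):
        rec = classify_pair(focal, partner)
        assert rec.category == category
        assert rec.orientation == orientation
        assert rec.subclass_label == label

    def test_intergenic_distances_are_tss_to_tss(self):
        rec = classify_pair(lnc("l", [(500, 900)], "-"), pcg("p", [(1000, 2000)], "+"))
        assert rec.distance_bp == 100  # TSS 900 vs TSS 1000
        assert rec.distance_span_bp == 100

    def test_divergent_transcription_factor_antisense_fixture(self):
        # divergent lncRNA/coding-gene pair 3,079 bp apart on chr15,
        # mirroring a cardiac transcription-factor locus with an
        # antisense lncRNA partner
        coding = pcg("LOC373988", [(12_317_331, 12_340_000)], "+", chrom="chr15")
        partner = lnc(
            "ENSGALG00010000570", [(12_296_000, 12_314_252)], "-", chrom="chr15"
        )
        rec = classify_pair(partner, coding)
        assert rec.orientation == "divergent"
        assert rec.category == "intergenic"
        assert rec.distance_bp == 3_079
        assert rec.pair_type == "LncPcg"

    def test_genic_antisense_orientation_is_flagged_as_convention(self):
        rec = classify_pair(
            lnc("l", [(1200, 1300)], "-"),
            pcg("p", [(1000, 1100), (1900, 2000)], "+"),
        )
        assert rec.genic_antisense_by_tss
        sense = classify_pair(
            lnc("l", [(1200, 1300)], "+"),
            pcg("p", [(1000, 1100), (1900, 2000)], "+"),
        )
        assert not sense.genic_antisense_by_tss

    def test_orientation_is_symmetric_between_members(self):
        for _, focal, partner, _, orientation, _ in TRUTH_TABLE:
            assert classify_pair(partner, focal).orientation == orientation

    def test_mirror_invariance(self):
        L = 10_000_000
        flip = {"+": "-", "-": "+"}
        for _, focal, partner, category, orientation, _ in TRUTH_TABLE:
            def mirror(g):
                exons = sorted(
                    (L - e.end, L - e.start)
                    for t in g.transcripts for e in t.exons
                )
                return make_gene(
                    g.gene_id, exons, flip[g.strand], biotype_class=g.biotype_class
                )
            rec = classify_pair(mirror(focal), mirror(partner))
            assert rec.category == category
            assert rec.orientation == orientation

    def test_cross_chromosome_pair_rejected(self):
        with pytest.raises(ValueError, match="different chromosomes"):
            classify_pair(lnc("l", [(0, 100)], "+"),
                          pcg("p", [(0, 100)], "+", chrom="chr2"))


class TestClosestPartner:
    def test_minimal_tss_distance_wins(self):
        focal = lnc("l", [(1000, 1400)], "+")
        candidates = Annotation("S", [
            focal,
            pcg("near", [(900, 950)], "+"),
            pcg("far", [(5000, 6000)], "+"),
        ])
        partner, distance = closest_partner(focal, candidates, "pcg")
        assert partner.gene_id == "near"
        assert distance == 100

    def test_partner_beyond_window_is_ignored(self):
        focal = lnc("l", [(1000, 1400)], "+")
        candidates = Annotation("S", [
            focal, pcg("far", [(151_000, 152_000)], "+"),
        ])
        assert closest_partner(focal, candidates, "pcg") is None

    def test_overlap_precedence_beats_tss_window(self):
        # nested candidate whose TSS is over 100 kb away still qualifies
        focal = pcg("host", [(0, 130_000)], "+")
        nested = lnc("inside", [(120_000, 121_000)], "-")
        decoy = lnc("outside", [(135_000, 136_000)], "+")
        candidates = Annotation("S", [focal, nested, decoy])
        partner, _ = closest_partner(focal, candidates, "lnc")
        assert partner.gene_id == "inside"

    def test_matches_brute_force_on_simulated_annotation(self):
        spec = FixtureSpec(seed=42, n_genes_per_source=(500, 10, 10),
                           overlap_fractions=(0.0, 0.0, 0.0))
        annotations, _ = simulate_annotations(spec)
        ann = annotations[0]
        genes = list(ann)
        rng = np.random.default_rng(0)
        for idx in rng.choice(len(genes), size=60, replace=False):
            focal = genes[int(idx)]
            for partner_class in ("pcg", "lnc"):
                got = closest_partner(focal, ann, partner_class)
                # brute force: overlap precedence, then min TSS distance
                overl, within = [], []
                for cand in genes:
                    if cand.gene_id == focal.gene_id:
                        continue
                    if cand.biotype_class != partner_class:
                        continue
                    if cand.chrom != focal.chrom:
                        continue
                    d = tss_distance(focal, cand)
                    spans_overlap = (
                        focal.start < cand.end and cand.start < focal.end
                    )
                    if spans_overlap:
                        overl.append((d, cand.gene_id))
                    elif d <= 100_000:
                        within.append((d, cand.gene_id))
                pool = overl or within
                if not pool:
                    assert got is None
                else:
                    d, gid = min(pool)
                    assert got is not None
                    assert (got[1], got[0].gene_id) == (d, gid)


class TestClassifyAll:
    def test_three_gene_toy_atlas_matches_hand_enumeration(self):
        genes = [
            lnc("l1", [(500, 900)], "-"),
            pcg("p1", [(1000, 2000)], "+"),
            pcg("p2", [(4000, 5000)], "+"),
        ]
        ann = Annotation("S", genes)
        records = classify_all(ann, focal_classes=("lnc",), partner_classes=("pcg",))
        assert len(records) == 1
        rec = records[0]
        assert (rec.focal_gene_id, rec.partner_gene_id) == ("l1", "p1")
        assert rec.orientation == "divergent"

    def test_single_gene_atlas_yields_no_records(self):
        ann = Annotation("S", [lnc("l1", [(0, 100)], "+")])
        assert classify_all(ann) == []

    def test_sole_member_of_class_still_pairs_with_other_classes(self):
        genes = [lnc("l1", [(500, 900)], "-"), pcg("p1", [(1000, 2000)], "+")]
        ann = Annotation("S", genes)
        records = classify_all(ann, focal_classes=("lnc",),
                               partner_classes=("lnc", "pcg"))
        assert [r.partner_gene_id for r in records] == ["p1"]

    def test_planted_fixture_geometries_classify_as_planted(self, default_fixture):
        ann = default_fixture["atlas"].annotation
        truth = default_fixture["truth"]
        for p in truth.planted_pairs:
            rec = classify_pair(ann.genes[p["gene_a"]], ann.genes[p["gene_b"]])
            exp = p["expected"]
            assert rec.category == exp["category"]
            assert rec.orientation == exp["orientation"]
            assert rec.distance_bp == exp["distance_bp"]
            assert rec.subclass_label == exp["subclass_label"]
            # and the planted partner is indeed the closest one
            partner, _ = closest_partner(
                ann.genes[p["gene_a"]], ann, "pcg"
            )
            assert partner.gene_id == p["gene_b"]
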