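"""Positional classification of gene pairs.

Each gene of interest is paired with its closest protein-coding or
lncRNA partner within a TSS-to-TSS window (default 100 kb) and the pair
is classified as genic (span overlap) or intergenic, and as sense
(same strand), divergent (head-to-head) or convergent (tail-to-tail).
Genic pairs carry an exonic/intronic x nested/overlapping sub-label.

Subclass label grammar::

    <focalClass>g(SS|DIV|CONV)(in|ex)(Nest|Ovlp)   genic
    <focalClass>g(SS|DIV|CONV)inter                intergenic

e.g. ``lncgSSinNest``: a lncRNA nested, same-strand, in an intron of its
partner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .merge import MergedAtlas, _interval_intersection_bp
from .models import Annotation, GeneModel


def _spans_overlap(a: GeneModel, b: GeneModel) -> bool:
    """Any-strand span intersection on the same chromosome."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def tss_distance(a: GeneModel, b: GeneModel) -> Optional[int]:
    """Minimal |TSS_a - TSS_b| over all transcript pairs; None across chroms."""
    if a.chrom != b.chrom:
        return None
    return min(abs(ta - tb) for ta in a.tss_set for tb in b.tss_set)


def span_gap(a: GeneModel, b: GeneModel) -> int:
    """bp between the two spans; 0 when they touch or overlap."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


@dataclass
class PairClassification:
    focal_gene_id: str
    partner_gene_id: str
    pair_type: str  # focal biotype then partner biotype, e.g. LncPcg
    category: str  # genic | intergenic
    orientation: str  # sense | divergent | convergent
    subclass_label: str
    distance_bp: int  # min TSS-to-TSS distance; 0 for genic pairs
    distance_span_bp: int  # gap between spans (0 when overlapping)
    partner_name: Optional[str] = None
    genic_antisense_by_tss: bool = False  # orientation inferred for overlapping pairs


def _class_token(biotype_class: str) -> str:
    return biotype_class[0].upper() + biotype_class[1:]


def _orientation(focal: GeneModel, partner: GeneModel) -> tuple[str, bool]:
    """sense / divergent / convergent, plus a flag for genic antisense pairs.

    Opposite-strand geometry: head-to-head (divergent) when the '-' gene's
    TSS lies left of the '+' gene's TSS, tail-to-tail (convergent) when it
    lies right.  For overlapping (genic) pairs this TSS rule is a
    convention, flagged in the returned bool.
    """
    if focal.strand == partner.strand:
        return "sense", False
    plus, minus = (focal, partner) if focal.strand == "+" else (partner, focal)
    plus_tss = min(plus.tss_set)
    minus_tss = max(minus.tss_set)
    orientation = "divergent" if minus_tss <= plus_tss else "convergent"
    return orientation, _spans_overlap(focal, partner)


def classify_pair(focal: GeneModel, partner: GeneModel) -> PairClassification:
    """Classify one (focal, partner) pair; both must share a chromosome."""
    if focal.chrom != partner.chrom:
        raise ValueError(
            f"{focal.gene_id} and {partner.gene_id} are on different chromosomes"
        )
    genic = _spans_overlap(focal, partner)
    orientation, tss_flagged = _orientation(focal, partner)
    orient_token = {"sense": "SS", "divergent": "DIV", "convergent": "CONV"}[
        orientation
    ]
    focal_token = focal.biotype_class + "g"

    if genic:
        exonic = (
            _interval_intersection_bp(focal.exon_union(), partner.exon_union()) > 0
        )
        nested = (partner.start <= focal.start and focal.end <= partner.end) or (
            focal.start <= partner.start and partner.end <= focal.end
        )
        label = (
            focal_token
            + orient_token
            + ("ex" if exonic else "in")
            + ("Nest" if nested else "Ovlp")
        )
        distance = 0
    else:
        label = focal_token + orient_token + "inter"
        distance = tss_distance(focal, partner)

    return PairClassification(
        focal_gene_id=focal.gene_id,
        partner_gene_id=partner.gene_id,
        pair_type=_class_token(focal.biotype_class) + _class_token(partner.biotype_class),
        category="genic" if genic else "intergenic",
        orientation=orientation,
        subclass_label=label,
        distance_bp=distance,
        distance_span_bp=span_gap(focal, partner),
        partner_name=partner.gene_name,
        genic_antisense_by_tss=tss_flagged,
    )


def closest_partner(
    focal: GeneModel,
    candidates: Annotation,
    partner_class: str,
    window_bp: int = 100_000,
) -> Optional[tuple[GeneModel, int]]:
    """The closest candidate of ``partner_class`` to ``focal``.

    Distance is the minimal TSS-to-TSS distance over transcript pairs on
    the same chromosome.  A candidate whose span overlaps the focal span
    (any strand) qualifies regardless of TSS distance and takes
    precedence over non-overlapping ones.  Ties break on smaller
    distance then lexicographic gene_id.  The focal gene itself is never
    returned.
    """
    overlapping: list[tuple[int, str, GeneModel]] = []
    within: list[tuple[int, str, GeneModel]] = []
    for cand in candidates:
        if cand.gene_id == focal.gene_id or cand.biotype_class != partner_class:
            continue
        if cand.chrom != focal.chrom:
            continue
        d = tss_distance(focal, cand)
        if _spans_overlap(focal, cand):
            overlapping.append((d, cand.gene_id, cand))
        elif d <= window_bp:
            within.append((d, cand.gene_id, cand))
    pool = overlapping if overlapping else within
    if not pool:
        return None
    d, _, cand = min(pool, key=lambda t: (t[0], t[1]))
    return cand, d


def classify_all(
    atlas: MergedAtlas | Annotation,
    focal_classes: Sequence[str] = ("pcg", "lnc", "mirna", "smallrna"),
    partner_classes: Sequence[str] = ("pcg", "lnc"),
    window_bp: int = 100_000,
) -> list[PairClassification]:
    """Classify every focal gene against its closest partner per class.

    One record per (focal gene, partner class) with a qualifying partner;
    deterministic order (focal chrom, start, gene_id, partner class).
    """
    ann = atlas.annotation if isinstance(atlas, MergedAtlas) else atlas
    records: list[PairClassification] = []
    focal_genes = sorted(
        (g for g in ann if g.biotype_class in set(focal_classes)),
        key=lambda g: (g.chrom, g.start, g.gene_id),
    )
    for focal in focal_genes:
        for partner_class in partner_classes:
            hit = closest_partner(focal, ann, partner_class, window_bp)
            if hit is None:
                continue
            partner, _ = hit
            records.append(classify_pair(focal, partner))
    return records
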