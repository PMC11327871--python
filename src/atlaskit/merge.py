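"""Sequential multi-source annotation merging.

Sources are aggregated in a fixed priority order, biotype class by
biotype class: a candidate gene enters the growing atlas only if none of
its exonic bases overlap an already-retained gene on the same strand.
Rejected candidates are recorded as identifier correspondences against
the retained gene they share the most exonic bases with, and every
retained locus accumulates the set of sources that independently support
it (its repeatability).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .models import Annotation, GeneModel, BIOTYPE_CLASSES

logger = logging.getLogger(__name__)

DEFAULT_CLASS_ORDER = ("pcg", "lnc", "mirna", "smallrna", "other")


@dataclass
class MergePolicy:
    """Order and scope of the sequential merge.

    overlap_scope 'any_class' rejects a candidate overlapping any retained
    gene; 'same_class' only tests retained genes of the candidate's own
    biotype class.
    """

    source_order: tuple[str, ...]
    biotype_class_order: tuple[str, ...] = DEFAULT_CLASS_ORDER
    overlap_scope: str = "any_class"

    def __post_init__(self):
        self.source_order = tuple(self.source_order)
        self.biotype_class_order = tuple(self.biotype_class_order)
        if len(set(self.source_order)) != len(self.source_order):
            raise ValueError("source_order contains duplicates")
        if sorted(self.biotype_class_order) != sorted(set(self.biotype_class_order)):
            raise ValueError("biotype_class_order contains duplicates")
        unknown = set(self.biotype_class_order) - set(BIOTYPE_CLASSES)
        if unknown:
            raise ValueError(f"unknown biotype classes: {unknown}")
        if self.overlap_scope not in ("any_class", "same_class"):
            raise ValueError(f"bad overlap_scope {self.overlap_scope!r}")


@dataclass
class CorrespondenceRow:
    rejected_gene_id: str
    rejected_source: str
    retained_gene_id: str
    shared_exonic_bp: int


@dataclass
class MergedAtlas:
    annotation: Annotation
    provenance: dict[str, str]
    correspondence: list[CorrespondenceRow]
    repeatability: dict[str, set[str]] = field(default_factory=dict)


def _interval_intersection_bp(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> int:
    """Total bp of intersection of two sorted, merged interval lists."""
    i = j = shared = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            shared += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return shared


def genes_exonically_overlap(a: GeneModel, b: GeneModel) -> int:
    """Shared exonic bp between two genes; 0 unless same chrom and strand."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return 0
    return _interval_intersection_bp(a.exon_union(), b.exon_union())


def merge_annotations(
    sources: list[Annotation], policy: MergePolicy
) -> MergedAtlas:
    """Build the enriched atlas from ``sources`` under ``policy``.

    Iterates biotype classes in ``policy.biotype_class_order``; within
    each class iterates sources in ``policy.source_order``.  Candidates
    within a source are taken in (chrom, start, gene_id) order for
    determinism.  Duplicate gene_ids across sources are namespaced as
    ``"<source>:<gene_id>"`` with a warning.
    """
    by_tag = {a.source_tag: a for a in sources}
    if set(by_tag) != set(policy.source_order):
        raise ValueError(
            f"source tags {sorted(by_tag)} do not match policy order "
            f"{list(policy.source_order)}"
        )

    merged = Annotation("merged")
    provenance: dict[str, str] = {}
    correspondence: list[CorrespondenceRow] = []
    repeatability: dict[str, set[str]] = {}
    # retained gene_id in merged -> original model (for overlap arithmetic)
    retained_models: dict[str, GeneModel] = {}

    def overlapping_retained(cand: GeneModel, scope: str) -> list[tuple[str, int]]:
        hits = set()
        for s, e in cand.exon_union():
            hits |= merged.query_exons(cand.chrom, s, e, cand.strand)
        out = []
        for gid in hits:
            g = retained_models[gid]
            if scope == "same_class" and g.biotype_class != cand.biotype_class:
                continue
            bp = genes_exonically_overlap(cand, g)
            if bp >= 1:
                out.append((gid, bp))
        return out

    for biotype_class in policy.biotype_class_order:
        for tag in policy.source_order:
            ann = by_tag[tag]
            candidates = sorted(
                ann.genes_by_class(biotype_class),
                key=lambda g: (g.chrom, g.start, g.gene_id),
            )
            for cand in candidates:
                hits = overlapping_retained(cand, policy.overlap_scope)
                if hits:
                    # attach to the retained gene sharing the most bp;
                    # ties broken by lowest (chrom, start, gene_id)
                    best_gid, best_bp = min(
                        hits,
                        key=lambda h: (
                            -h[1],
                            retained_models[h[0]].chrom,
                            retained_models[h[0]].start,
                            h[0],
                        ),
                    )
                    correspondence.append(
                        CorrespondenceRow(cand.gene_id, tag, best_gid, best_bp)
                    )
                else:
                    gid = cand.gene_id
                    if gid in merged:
                        gid = f"{tag}:{gid}"
                        logger.warning(
                            "duplicate gene_id %r: retained as %r", cand.gene_id, gid
                        )
                    model = GeneModel(
                        gene_id=gid,
                        gene_name=cand.gene_name,
                        biotype_class=cand.biotype_class,
                        source=tag,
                        transcripts=cand.transcripts,
                    )
                    merged.add_gene(model)
                    retained_models[gid] = model
                    provenance[gid] = tag

    # Repeatability: every source model with >=1 bp overlap supports the locus.
    for gid, model in retained_models.items():
        repeatability[gid] = set()
    for tag in policy.source_order:
        for gene in by_tag[tag]:
            hits = set()
            for s, e in gene.exon_union():
                hits |= merged.query_exons(gene.chrom, s, e, gene.strand)
            for gid in hits:
                if genes_exonically_overlap(gene, retained_models[gid]) >= 1:
                    repeatability[gid].add(tag)

    return MergedAtlas(
        annotation=merged,
        provenance=provenance,
        correspondence=correspondence,
        repeatability=repeatability,
    )


def correspondence_table(atlas: MergedAtlas) -> pd.DataFrame:
    """One row per retained gene: its source, alternate ids per source,
    and the repeatability count (number of supporting sources)."""
    alt: dict[str, dict[str, list[str]]] = {}
    for row in atlas.correspondence:
        alt.setdefault(row.retained_gene_id, {}).setdefault(
            row.rejected_source, []
        ).append(row.rejected_gene_id)

    records = []
    for gene in sorted(
        atlas.annotation, key=lambda g: (g.chrom, g.start, g.gene_id)
    ):
        gid = gene.gene_id
        groups = alt.get(gid, {})
        alt_str = "; ".join(
            f"{src}:" + ",".join(sorted(ids))
            for src, ids in sorted(groups.items())
        )
        records.append(
            {
                "gene_id": gid,
                "gene_name": gene.gene_name or "",
                "source": atlas.provenance[gid],
                "biotype_class": gene.biotype_class,
                "chrom": gene.chrom,
                "start": gene.start,
                "end": gene.end,
                "strand": gene.strand,
                "alternate_ids": alt_str,
                "repeatability": len(atlas.repeatability.get(gid, {gene.source})),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "gene_id", "gene_name", "source", "biotype_class", "chrom",
            "start", "end", "strand", "alternate_ids", "repeatability",
        ],
    )
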