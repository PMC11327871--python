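"""Region definition, identifier resolution and the table-filter grammar.

Regions can be anchored on a gene (span plus independent upstream and
downstream offsets) or on a point; gene lookup works across retained
ids, alternate-source ids and gene names via the merge correspondence.

Filters combine as AND across criteria; within one criterion, comma-
separated values combine as OR.  ``contains`` is case-insensitive
substring matching; ``greater``/``lower`` apply to numeric columns only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .merge import MergedAtlas
from .models import Annotation, GeneModel


@dataclass
class Region:
    chrom: str
    start: int  # 0-based half-open
    end: int
    origin: str = "point"  # gene_id or "point"
    upstream_offset: int = 0
    downstream_offset: int = 0

    def __post_init__(self):
        if self.start < 0:
            raise ValueError("region start must be >= 0")
        if not self.start < self.end:
            raise ValueError(f"empty region [{self.start}, {self.end})")


OPERATORS = ("equals", "not_equals", "contains", "not_contains", "greater", "lower")


@dataclass
class FilterCriterion:
    column: str
    operator: str
    values: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.operator not in OPERATORS:
            raise ValueError(f"unknown operator {self.operator!r}")
        if not self.values:
            raise ValueError("criterion needs at least one value")

    @classmethod
    def parse(cls, column: str, operator: str, raw: str) -> "FilterCriterion":
        """Split a raw value string on commas (the OR delimiter)."""
        values = [v.strip() for v in raw.split(",") if v.strip()]
        return cls(column, operator, values)


def define_region(
    anchor,
    up: int,
    down: int,
    atlas: MergedAtlas | Annotation | None = None,
) -> Region:
    """A region around a gene (id or name) or a (chrom, pos) point.

    Gene anchors span ``[gene.start - up, gene.end + down)``; point
    anchors ``[pos - up, pos + down)``; both clipped at 0.  Offsets are
    independent per side.  Unknown gene anchors raise with near-miss
    suggestions.
    """
    if isinstance(anchor, tuple):
        chrom, pos = anchor
        start = max(0, pos - up)
        end = pos + down
        if end <= start:  # a point query with down=0 still needs width
            end = start + 1
        return Region(chrom, start, end, "point", up, down)

    ann = atlas.annotation if isinstance(atlas, MergedAtlas) else atlas
    if ann is None:
        raise ValueError("gene anchor requires an atlas")
    gene = _find_gene(anchor, ann)
    if gene is None:
        near = [
            g.gene_id
            for g in ann
            if anchor.lower() in g.gene_id.lower()
            or (g.gene_name and anchor.lower() in g.gene_name.lower())
        ][:5]
        raise KeyError(
            f"unknown gene {anchor!r}"
            + (f"; close matches: {', '.join(near)}" if near else "")
        )
    return Region(
        gene.chrom,
        max(0, gene.start - up),
        gene.end + down,
        origin=gene.gene_id,
        upstream_offset=up,
        downstream_offset=down,
    )


def _find_gene(token: str, ann: Annotation) -> Optional[GeneModel]:
    if token in ann:
        return ann.genes[token]
    for g in ann:
        if g.gene_name == token:
            return g
    return None


def genes_in_region(
    region: Region,
    atlas: MergedAtlas | Annotation,
    biotype_filter: Optional[set[str]] = None,
) -> list[GeneModel]:
    """Genes whose span intersects the region (any strand), sorted by start."""
    ann = atlas.annotation if isinstance(atlas, MergedAtlas) else atlas
    hits = [
        g
        for g in ann
        if g.chrom == region.chrom
        and g.start < region.end
        and region.start < g.end
        and (biotype_filter is None or g.biotype_class in biotype_filter)
    ]
    return sorted(hits, key=lambda g: (g.start, g.gene_id))


def apply_filters(
    table: pd.DataFrame, criteria: Sequence[FilterCriterion]
) -> pd.DataFrame:
    """AND of criteria; OR across each criterion's comma values."""
    mask = pd.Series(True, index=table.index)
    for crit in criteria:
        if crit.column not in table.columns:
            raise KeyError(f"unknown column {crit.column!r}")
        col = table[crit.column]
        if crit.operator in ("greater", "lower"):
            if not pd.api.types.is_numeric_dtype(col):
                raise TypeError(
                    f"operator {crit.operator!r} needs a numeric column, "
                    f"{crit.column!r} is {col.dtype}"
                )
            try:
                numbers = [float(v) for v in crit.values]
            except ValueError as exc:
                raise TypeError(
                    f"non-numeric value for {crit.operator!r}: {crit.values}"
                ) from exc
            if crit.operator == "greater":
                crit_mask = pd.concat(
                    [col > n for n in numbers], axis=1
                ).any(axis=1)
            else:
                crit_mask = pd.concat(
                    [col < n for n in numbers], axis=1
                ).any(axis=1)
        else:
            as_str = col.astype(str)
            if crit.operator in ("equals", "not_equals"):
                if pd.api.types.is_numeric_dtype(col):
                    hit = pd.concat(
                        [col == float(v) for v in crit.values], axis=1
                    ).any(axis=1)
                else:
                    hit = as_str.isin(crit.values)
                crit_mask = hit if crit.operator == "equals" else ~hit
            else:  # contains / not_contains, case-insensitive substring
                lowered = as_str.str.lower()
                hit = pd.concat(
                    [lowered.str.contains(v.lower(), regex=False) for v in crit.values],
                    axis=1,
                ).any(axis=1)
                crit_mask = hit if crit.operator == "contains" else ~hit
        mask &= crit_mask
    return table[mask]


@dataclass
class Resolution:
    token: str
    status: str  # resolved | unresolved | ambiguous
    gene_ids: list[str] = field(default_factory=list)


def resolve_identifiers(
    tokens: Sequence[str], atlas: MergedAtlas
) -> dict[str, Resolution]:
    """Resolve tokens against retained ids, alternate ids and gene names.

    Exact matches are preferred over case-insensitive ones; a token
    hitting several distinct genes is reported ambiguous, never silently
    picked; unresolved tokens are reported, never dropped.
    """
    ann = atlas.annotation
    exact: dict[str, set[str]] = {}
    folded: dict[str, set[str]] = {}

    def register(key: Optional[str], gid: str):
        if not key:
            return
        exact.setdefault(key, set()).add(gid)
        folded.setdefault(key.lower(), set()).add(gid)

    for g in ann:
        register(g.gene_id, g.gene_id)
        register(g.gene_name, g.gene_id)
    for row in atlas.correspondence:
        register(row.rejected_gene_id, row.retained_gene_id)

    out: dict[str, Resolution] = {}
    for token in tokens:
        hits = exact.get(token) or folded.get(token.lower()) or set()
        if not hits:
            out[token] = Resolution(token, "unresolved")
        elif len(hits) == 1:
            out[token] = Resolution(token, "resolved", sorted(hits))
        else:
            out[token] = Resolution(token, "ambiguous", sorted(hits))
    return out
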