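"""Co-expression of gene pairs across tissues or samples.

Rank correlation is the natural choice for median expression profiles:
robust to the heavy right tail of TPM values and invariant to monotone
transforms.  Kendall's tau-b (tie-corrected) is the default because
per-tissue medians contain ties (zeros); Spearman's rho is available as
an option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .expression import TissueProfile
from .models import Annotation, GeneModel
from .pairs import PairClassification, tss_distance

logger = logging.getLogger(__name__)


@dataclass
class CoexpressionRecord:
    gene_a: str
    gene_b: str
    method: str  # kendall | spearman
    correlation: Optional[float]  # None when undefined (constant vector, n < 3)
    n_points: int
    scope: str = "tissues"  # tissues | samples
    same_chromosome: Optional[bool] = None
    within_distance: Optional[bool] = None


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Kendall's tau-b: (C - D) / sqrt((n0 - n1)(n0 - n2)).

    C/D are concordant/discordant pair counts and n1, n2 the tied-pair
    counts in x and y.  None when either vector is constant.
    """
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if len(set(x)) < 2 or len(set(y)) < 2:
        return None
    t = stats.kendalltau(x, y, variant="b").statistic
    return None if math.isnan(t) else float(t)


def _spearman(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    if len(set(x)) < 2 or len(set(y)) < 2:
        return None
    r = stats.spearmanr(x, y).statistic
    return None if math.isnan(r) else float(r)


_METHODS = {"kendall": kendall_tau_b, "spearman": _spearman}


def _aligned_vectors(
    a: TissueProfile, b: TissueProfile
) -> tuple[list[float], list[float]]:
    tissues = sorted(set(a.tissue_median) & set(b.tissue_median))
    return (
        [a.tissue_median[t] for t in tissues],
        [b.tissue_median[t] for t in tissues],
    )


def pair_coexpression(
    pairs: Sequence[PairClassification],
    profiles: Mapping[str, TissueProfile],
    method: str = "kendall",
) -> list[CoexpressionRecord]:
    """One co-expression record per classified pair, across tissues.

    Pairs with a missing profile yield a record with None correlation.
    """
    corr_fn = _METHODS[method]
    records = []
    for p in pairs:
        pa = profiles.get(p.focal_gene_id)
        pb = profiles.get(p.partner_gene_id)
        if pa is None or pb is None:
            logger.warning(
                "missing profile for pair (%s, %s)", p.focal_gene_id, p.partner_gene_id
            )
            records.append(
                CoexpressionRecord(
                    p.focal_gene_id, p.partner_gene_id, method, None, 0
                )
            )
            continue
        x, y = _aligned_vectors(pa, pb)
        corr = corr_fn(x, y) if len(x) >= 3 else None
        records.append(
            CoexpressionRecord(
                p.focal_gene_id, p.partner_gene_id, method, corr, len(x)
            )
        )
    return records


def top_correlated(
    focal: str,
    profiles: Mapping[str, TissueProfile],
    k: int = 50,
    method: str = "kendall",
    annotation: Optional[Annotation] = None,
    distance_threshold: int = 100_000,
) -> list[CoexpressionRecord]:
    """The k genes most correlated with ``focal`` across tissues.

    Every other profiled gene is scored and the list is returned in
    descending correlation order (undefined correlations sort last).
    With an annotation, records carry same-chromosome and
    within-distance flags (minimal TSS distance vs the threshold).
    """
    if focal not in profiles:
        raise KeyError(f"unknown focal gene {focal!r}")
    corr_fn = _METHODS[method]
    focal_prof = profiles[focal]
    focal_gene: Optional[GeneModel] = None
    if annotation is not None and focal in annotation:
        focal_gene = annotation.genes[focal]

    records = []
    for gid, prof in profiles.items():
        if gid == focal:
            continue
        x, y = _aligned_vectors(focal_prof, prof)
        corr = corr_fn(x, y) if len(x) >= 3 else None
        same_chrom = within = None
        if focal_gene is not None and annotation is not None and gid in annotation:
            other = annotation.genes[gid]
            same_chrom = other.chrom == focal_gene.chrom
            if same_chrom:
                d = tss_distance(focal_gene, other)
                within = d is not None and d <= distance_threshold
            else:
                within = False
        records.append(
            CoexpressionRecord(
                focal, gid, method, corr, len(x),
                same_chromosome=same_chrom, within_distance=within,
            )
        )
    records.sort(
        key=lambda r: (
            r.correlation is None,
            -(r.correlation if r.correlation is not None else 0.0),
            r.gene_b,
        )
    )
    return records[:k]


def sample_coexpression(
    gene_a: str,
    gene_b: str,
    tpm,
    samples,
    tissue: str,
    method: str = "kendall",
) -> CoexpressionRecord:
    """Correlation over all samples of one tissue, pooled across projects."""
    cols = [s.sample_id for s in samples if s.tissue == tissue]
    x = tpm.loc[gene_a, cols].to_numpy(dtype=float)
    y = tpm.loc[gene_b, cols].to_numpy(dtype=float)
    corr = _METHODS[method](list(x), list(y)) if len(cols) >= 3 else None
    return CoexpressionRecord(
        gene_a, gene_b, method, corr, len(cols), scope="samples"
    )
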