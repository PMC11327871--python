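"""Expression normalization, aggregation and expressed-gene flags.

The pipeline mirrors a multi-project tissue atlas: per-sample counts are
TPM-normalized (within-sample, length- and depth-corrected), scaled
between samples with TMM factors, aggregated into per-tissue medians by
a two-stage median (samples within each (tissue, project), then projects
within each tissue), and flagged as expressed / highly expressed.

A gene is *expressed* when (i) its per-tissue median is >= 0.1 TPM in at
least one tissue and (ii) in at least one (tissue, project) cell, at
least 50% of samples jointly have >= 6 reads, TPM >= 0.1 and
TMM-normalized expression >= 0.1.  *Highly expressed* additionally
requires a tissue median >= 1 TPM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SampleMeta:
    sample_id: str
    project: str
    tissue: str
    sex: Optional[str] = None
    age: Optional[str] = None

    def __post_init__(self):
        if not self.tissue or not self.project:
            raise ValueError(
                f"sample {self.sample_id}: tissue and project must be non-empty"
            )


def meta_frame(samples: Sequence[SampleMeta]) -> pd.DataFrame:
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in metadata")
    return pd.DataFrame(
        {
            "sample_id": ids,
            "project": [s.project for s in samples],
            "tissue": [s.tissue for s in samples],
            "sex": [s.sex for s in samples],
            "age": [s.age for s in samples],
        }
    ).set_index("sample_id")


@dataclass
class TissueProfile:
    """Per-gene per-tissue median TPM after project aggregation."""

    gene_id: str
    tissue_median: dict[str, float]

    @property
    def n_tissues(self) -> int:
        return len(self.tissue_median)


@dataclass
class ExpressionMatrix:
    """Sample-level expression with metadata.

    ``counts`` and ``tpm`` are genes x samples DataFrames with identical
    index/columns; ``tmm_scaled`` (CPM on TMM-effective library sizes) is
    derived lazily by :meth:`compute_tmm_scaled`.
    """

    samples: list[SampleMeta]
    tpm: pd.DataFrame
    counts: Optional[pd.DataFrame] = None
    tmm_scaled: Optional[pd.DataFrame] = None

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        if list(self.tpm.columns) != ids:
            raise ValueError("tpm columns must match sample metadata order")
        if self.counts is not None:
            if not self.counts.index.equals(self.tpm.index) or list(
                self.counts.columns
            ) != ids:
                raise ValueError("counts and tpm dimensions/labels differ")

    @property
    def genes(self) -> list[str]:
        return list(self.tpm.index)

    def compute_tmm_scaled(self, **tmm_kwargs) -> pd.DataFrame:
        """CPM with TMM-effective library sizes (libsize x TMM factor)."""
        if self.counts is None:
            raise ValueError("counts are required to derive TMM-scaled expression")
        factors = tmm_factors(self.counts, **tmm_kwargs)
        lib = self.counts.sum(axis=0)
        eff = lib * pd.Series(factors)
        self.tmm_scaled = self.counts / eff * 1e6
        return self.tmm_scaled


def tpm_normalize(
    counts: pd.DataFrame, lengths: Mapping[str, float]
) -> pd.DataFrame:
    """TPM: reads per kilobase of gene, rescaled to sum to 1e6 per sample.

    All-zero samples stay all-zero and are logged.  Raises if a gene is
    missing from ``lengths`` or has a non-positive length.
    """
    missing = [g for g in counts.index if g not in lengths]
    if missing:
        raise KeyError(f"missing effective length for gene(s): {missing[:5]}")
    length_kb = pd.Series({g: lengths[g] for g in counts.index}) / 1e3
    if (length_kb <= 0).any():
        bad = length_kb.index[length_kb <= 0][0]
        raise ValueError(f"non-positive length for gene {bad}")
    rate = counts.div(length_kb, axis=0)
    denom = rate.sum(axis=0)
    zero_cols = denom[denom == 0].index
    if len(zero_cols):
        logger.warning("all-zero sample(s) left as zero TPM: %s", list(zero_cols))
        denom = denom.replace(0, np.nan)
    tpm = rate.div(denom, axis=1) * 1e6
    return tpm.fillna(0.0)


def _f75(counts: pd.DataFrame) -> pd.Series:
    lib = counts.sum(axis=0)
    return (counts / lib).quantile(0.75, axis=0)


def tmm_factors(
    counts: pd.DataFrame,
    reference: Optional[str] = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> dict[str, float]:
    """Trimmed-mean-of-M-values scaling factors, one per sample.

    For each sample vs the reference, per-gene log2 fold changes (M) and
    average log2 abundances (A) are computed on library-size-scaled
    counts; genes in the upper/lower ``trim_m`` tail of M or ``trim_a``
    tail of A are discarded and the factor is 2 to the precision-weighted
    mean of the remaining M values.  Factors are rescaled so their
    geometric mean is 1.  The default reference is the sample whose
    scaled 75th percentile is closest to the mean of those percentiles.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = lib.index[lib == 0][0]
        raise ValueError(f"sample {bad} has zero total counts")
    f75 = _f75(counts)
    if reference is None:
        reference = (f75 - f75.mean()).abs().idxmin()
    elif reference not in counts.columns:
        raise KeyError(f"unknown reference sample {reference!r}")

    ref = counts[reference].to_numpy(dtype=float)
    nref = lib[reference]
    log_factors: dict[str, float] = {}
    for sample in counts.columns:
        obs = counts[sample].to_numpy(dtype=float)
        nobs = lib[sample]
        keep = (obs > 0) & (ref > 0)
        if sample == reference or not keep.any():
            log_factors[sample] = 0.0
            continue
        o, r = obs[keep], ref[keep]
        m = np.log2((o / nobs) / (r / nref))
        a = 0.5 * np.log2((o / nobs) * (r / nref))
        # asymptotic (delta-method) inverse variance of M
        w = (nobs - o) / (nobs * o) + (nref - r) / (nref * r)
        if np.abs(m).max() < 1e-6:  # identical composition
            log_factors[sample] = 0.0
            continue
        n = len(m)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep2.any() or w[keep2].sum() == 0:
            log_factors[sample] = 0.0
            continue
        f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
        log_factors[sample] = 0.0 if not np.isfinite(f) else f

    mean_log = float(np.mean(list(log_factors.values())))
    return {s: float(2 ** (lf - mean_log)) for s, lf in log_factors.items()}


def tissue_medians(
    tpm: pd.DataFrame, samples: Sequence[SampleMeta]
) -> dict[str, TissueProfile]:
    """Two-stage median: samples within (tissue, project), then projects.

    Tissues with zero samples are simply absent from the profiles.
    """
    meta = meta_frame(samples)
    if list(tpm.columns) != list(meta.index):
        raise ValueError("tpm columns must match sample metadata order")
    # stage 1: per (tissue, project) median across samples
    cell_medians = tpm.T.groupby(
        [meta["tissue"], meta["project"]], sort=True
    ).median()
    # stage 2: per tissue median across projects
    tissue_med = cell_medians.groupby(level="tissue", sort=True).median().T
    return {
        gid: TissueProfile(gid, row.to_dict())
        for gid, row in tissue_med.iterrows()
    }


@dataclass
class GeneFlags:
    gene_id: str
    expressed: bool
    highly_expressed: bool
    supporting: list[tuple[str, str]] = field(default_factory=list)


def expression_flags(
    matrix: ExpressionMatrix,
    profiles: Mapping[str, TissueProfile],
    min_tpm: float = 0.1,
    min_reads: int = 6,
    min_frac: float = 0.5,
    high_tpm: float = 1.0,
    strict_same_tissue: bool = False,
) -> dict[str, GeneFlags]:
    """Expressed / highly-expressed flags per gene.

    ``strict_same_tissue`` requires the (tissue, project) cell satisfying
    the per-sample condition to belong to a tissue whose median also
    meets ``min_tpm``; the default only requires both conditions to hold
    somewhere.
    """
    if matrix.counts is None:
        raise ValueError("counts are required for expression flags")
    if matrix.tmm_scaled is None:
        matrix.compute_tmm_scaled()
    meta = meta_frame(matrix.samples)
    cells = meta.groupby(["tissue", "project"], sort=True).groups

    counts = matrix.counts
    tpm = matrix.tpm
    tmm = matrix.tmm_scaled
    qualifies = (counts >= min_reads) & (tpm >= min_tpm) & (tmm >= min_tpm)

    # fraction of qualifying samples per gene per (tissue, project) cell
    frac_ok: dict[tuple[str, str], pd.Series] = {
        cell: qualifies[list(idx)].mean(axis=1) for cell, idx in cells.items()
    }

    out: dict[str, GeneFlags] = {}
    for gid in matrix.genes:
        prof = profiles.get(gid)
        medians = prof.tissue_median if prof else {}
        tissues_ok = {t for t, v in medians.items() if v >= min_tpm}
        supporting = [
            cell for cell, frac in frac_ok.items() if frac.loc[gid] >= min_frac
        ]
        if strict_same_tissue:
            supporting = [c for c in supporting if c[0] in tissues_ok]
        expressed = bool(tissues_ok) and bool(supporting)
        highly = expressed and max(medians.values(), default=0.0) >= high_tpm
        out[gid] = GeneFlags(gid, expressed, highly, sorted(supporting))
    return out
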