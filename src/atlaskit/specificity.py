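"""Tissue-specificity indicators: the tau index, break detection and
fold-change statistics.

tau for a gene with per-tissue medians x_t (t = 1..T):

    tau = sum_t (1 - x_t / max_t x_t) / (T - 1)

0 for uniform expression, 1 when a single tissue carries all expression.
The log10 variant applies log10(x + pseudocount) before normalizing.  A
gene is flagged tissue-specific (TS) when tau >= 0.90 (inclusive).

A *break* is a >= 2-fold drop between consecutive tissues once medians
are ranked in descending order; breaks partition the expressed tissues
into groups, and three fold-change statistics quantify the drop across
the first break.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import pandas as pd

from .expression import TissueProfile

TAU_THRESHOLD = 0.90
FC_THRESHOLD = 2.0
FLOOR_TPM = 0.1


def tau(
    profile: TissueProfile | Mapping[str, float],
    log10: bool = False,
    pseudocount: float = 1.0,
) -> Optional[float]:
    """The tau tissue-specificity index; None when all medians are zero."""
    medians = (
        profile.tissue_median if isinstance(profile, TissueProfile) else dict(profile)
    )
    if len(medians) < 2:
        raise ValueError(f"tau needs >= 2 tissues, got {len(medians)}")
    values = list(medians.values())
    if any(v < 0 for v in values):
        raise ValueError("negative expression value")
    if log10:
        values = [math.log10(v + pseudocount) for v in values]
    top = max(values)
    if top == 0:
        return None
    return sum(1.0 - v / top for v in values) / (len(values) - 1)


def ts_flag(tau_value: Optional[float], threshold: float = TAU_THRESHOLD) -> int:
    """1 iff tau >= threshold (inclusive); undefined tau maps to 0."""
    return int(tau_value is not None and tau_value >= threshold)


@dataclass
class BreakStructure:
    """Descending-rank partition of expressed tissues by >=2-fold drops.

    ``tissue_breaks`` lists tissue groups in rank order; ``fc_breaks``
    holds one fold change per break between consecutive groups.  Tissues
    below the expression floor form a trailing group separated by an
    implicit break whose FC is the observed ratio (inf over zero).
    """

    nb_breaks: int
    fc_breaks: list[float]
    tissue_breaks: list[list[str]]
    all_below_floor: bool = False

    @property
    def tissue_first_break(self) -> list[str]:
        return self.tissue_breaks[0] if self.tissue_breaks else []

    @property
    def tissue_nb_first_break(self) -> int:
        return len(self.tissue_first_break)


def detect_breaks(
    profile: TissueProfile | Mapping[str, float],
    fc_threshold: float = FC_THRESHOLD,
    floor_tpm: float = FLOOR_TPM,
) -> BreakStructure:
    """Rank tissues by median descending and split at >= fc_threshold drops.

    Ties are ordered by tissue name (a tie has FC 1 and never breaks).
    Only tissues at or above ``floor_tpm`` enter the scan; the rest, if
    any, are appended as a final group behind an implicit break.
    """
    medians = (
        profile.tissue_median if isinstance(profile, TissueProfile) else dict(profile)
    )
    ranked = sorted(medians.items(), key=lambda kv: (-kv[1], kv[0]))
    expressed = [(t, v) for t, v in ranked if v >= floor_tpm]
    below = [(t, v) for t, v in ranked if v < floor_tpm]
    if not expressed:
        return BreakStructure(0, [], [], all_below_floor=True)

    groups: list[list[str]] = [[expressed[0][0]]]
    fcs: list[float] = []
    for (t_hi, v_hi), (t_lo, v_lo) in zip(expressed, expressed[1:]):
        ratio = v_hi / v_lo  # v_lo >= floor > 0 when floor > 0
        if ratio >= fc_threshold:
            fcs.append(ratio)
            groups.append([t_lo])
        else:
            groups[-1].append(t_lo)
    if below:
        v_hi = expressed[-1][1]
        v_lo = below[0][1]
        fcs.append(v_hi / v_lo if v_lo > 0 else math.inf)
        groups.append([t for t, _ in below])
    return BreakStructure(len(fcs), fcs, groups)


@dataclass
class FcStatistics:
    fc_top1_top2: Optional[float]
    fc_first_break_low_to_top: Optional[float]
    fc_first_break_top_to_top: Optional[float]
    fc_first_break_median_group: Optional[float]


def _median(values: Sequence[float]) -> float:
    s = sorted(values)
    n = len(s)
    mid = n // 2
    return s[mid] if n % 2 else (s[mid - 1] + s[mid]) / 2.0


def fc_statistics(
    profile: TissueProfile | Mapping[str, float],
    breaks: BreakStructure,
) -> FcStatistics:
    """Top1/top2 FC and the three first-break fold changes.

    First-break FCs compare group 1 with group 2: (a) least expressed of
    group 1 over most expressed of group 2; (b) most expressed of both;
    (c) group medians.  All None when no break exists or a denominator
    is zero.
    """
    medians = (
        profile.tissue_median if isinstance(profile, TissueProfile) else dict(profile)
    )
    ranked = sorted(medians.values(), reverse=True)
    fc12 = None
    if len(ranked) >= 2 and ranked[1] > 0:
        fc12 = ranked[0] / ranked[1]

    if breaks.nb_breaks == 0 or len(breaks.tissue_breaks) < 2:
        return FcStatistics(fc12, None, None, None)
    g1 = [medians[t] for t in breaks.tissue_breaks[0]]
    g2 = [medians[t] for t in breaks.tissue_breaks[1]]

    def ratio(num: float, den: float) -> Optional[float]:
        return num / den if den > 0 else None

    return FcStatistics(
        fc_top1_top2=fc12,
        fc_first_break_low_to_top=ratio(min(g1), max(g2)),
        fc_first_break_top_to_top=ratio(max(g1), max(g2)),
        fc_first_break_median_group=ratio(_median(g1), _median(g2)),
    )


@dataclass
class TSMetrics:
    """All tissue-specificity indicators for one gene."""

    gene_id: str
    tau: Optional[float]
    tau_log10: Optional[float]
    is_ts: int
    is_ts_log10: int
    breaks: BreakStructure = field(default_factory=lambda: BreakStructure(0, [], []))
    fc: FcStatistics = field(
        default_factory=lambda: FcStatistics(None, None, None, None)
    )


def ts_metrics(
    profile: TissueProfile | Mapping[str, float],
    gene_id: str = "",
    tau_threshold: float = TAU_THRESHOLD,
    fc_threshold: float = FC_THRESHOLD,
    floor_tpm: float = FLOOR_TPM,
    pseudocount: float = 1.0,
) -> TSMetrics:
    """Compute every indicator for one per-tissue median profile."""
    if isinstance(profile, TissueProfile) and not gene_id:
        gene_id = profile.gene_id
    t_raw = tau(profile)
    t_log = tau(profile, log10=True, pseudocount=pseudocount)
    breaks = detect_breaks(profile, fc_threshold=fc_threshold, floor_tpm=floor_tpm)
    return TSMetrics(
        gene_id=gene_id,
        tau=t_raw,
        tau_log10=t_log,
        is_ts=ts_flag(t_raw, tau_threshold),
        is_ts_log10=ts_flag(t_log, tau_threshold),
        breaks=breaks,
        fc=fc_statistics(profile, breaks),
    )


#: Output column order; names mirror the atlas's published table.
TS_COLUMNS = [
    "gene_id", "expr_tau", "expr_tauLog10", "expr_isTS", "expr_isTSlog10",
    "expr_fcTop1Top2", "expr_nbBreaks", "expr_fcBreaks", "expr_tissueBreaks",
    "expr_tissueFirstBreak", "expr_tissueNbFirstBreak",
    "expr_fcFirstBreak_lowToTop", "expr_fcFirstBreak_topToTop",
    "expr_fcFirstBreak_medianGroup",
]


def ts_table(
    profiles: Mapping[str, TissueProfile], **kwargs
) -> pd.DataFrame:
    """TS metrics for every gene as a tidy DataFrame (one row per gene)."""
    rows = []
    for gid in profiles:
        m = ts_metrics(profiles[gid], gene_id=gid, **kwargs)
        rows.append(
            {
                "gene_id": gid,
                "expr_tau": m.tau,
                "expr_tauLog10": m.tau_log10,
                "expr_isTS": m.is_ts,
                "expr_isTSlog10": m.is_ts_log10,
                "expr_fcTop1Top2": m.fc.fc_top1_top2,
                "expr_nbBreaks": m.breaks.nb_breaks,
                "expr_fcBreaks": ",".join(f"{f:g}" for f in m.breaks.fc_breaks),
                "expr_tissueBreaks": "|".join(
                    ",".join(g) for g in m.breaks.tissue_breaks
                ),
                "expr_tissueFirstBreak": ",".join(m.breaks.tissue_first_break),
                "expr_tissueNbFirstBreak": m.breaks.tissue_nb_first_break,
                "expr_fcFirstBreak_lowToTop": m.fc.fc_first_break_low_to_top,
                "expr_fcFirstBreak_topToTop": m.fc.fc_first_break_top_to_top,
                "expr_fcFirstBreak_medianGroup": m.fc.fc_first_break_median_group,
            }
        )
    return pd.DataFrame(rows, columns=TS_COLUMNS)


def compare_ts_sets(
    flagged_sets: Mapping[str, set[str]]
) -> dict[frozenset[str], int]:
    """Exact Venn-partition counts for up to 6 flagged gene sets.

    Keys are frozensets of metric names; the value counts genes belonging
    to exactly those sets and no others.  Empty regions are included.
    """
    names = list(flagged_sets)
    if len(names) < 2:
        raise ValueError("need at least 2 sets")
    if len(names) > 6:
        raise ValueError("at most 6 sets supported")
    universe = set().union(*flagged_sets.values())
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions[frozenset(combo)] = 0
    for gene in universe:
        member = frozenset(n for n in names if gene in flagged_sets[n])
        regions[member] += 1
    return regions
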