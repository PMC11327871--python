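"""Synthetic annotations and expression matrices with known ground truth.

The generator emulates the structure of a multi-source, multi-project
tissue expression atlas at desk scale: several annotation sources with a
controlled fraction of exonically overlapping gene models, a tissue x
project sample design, planted tissue-specific genes (one dominant
tissue at a stated fold), and planted co-expressed gene pairs realized
both geometrically (exact pair configuration and distance) and in
expression (a shared per-tissue latent factor).

Every quantity derives from one :class:`numpy.random.Generator` seeded
from ``FixtureSpec.seed``: a fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .expression import SampleMeta, tpm_normalize
from .models import Annotation, ExonInterval, GeneModel, TranscriptModel, exonic_bases

#: (configuration, TSS distance bp) cycled over planted pairs; the
#: 3,079 bp divergent geometry mirrors a well-known transcription-factor /
#: antisense-lncRNA arrangement.
DEFAULT_PAIR_CONFIGS = (
    ("divergent", 3_079),
    ("convergent", 5_000),
    ("sense", 10_000),
    ("nested_intronic", 0),
    ("divergent", 100),
)


@dataclass
class FixtureSpec:
    """Parameters of one synthetic atlas.

    Defaults are a 1/10-scale image of a large atlas: 3 sources totalling
    ~500 genes, 8 tissues x 4 projects x 3 samples.  ``overlap_fractions``
    give, per later source, the fraction of its models that exonically
    overlap a source-1 gene on the same strand (the planted rejection
    set).
    """

    seed: int = 0
    n_chromosomes: int = 3
    source_tags: tuple[str, ...] = ("refA", "refB", "extC")
    n_genes_per_source: tuple[int, ...] = (300, 120, 80)
    overlap_fractions: tuple[float, ...] = (0.0, 0.4, 0.4)
    n_tissues: int = 8
    n_projects: int = 4
    samples_per_tissue_project: int = 3
    n_planted_ts: int = 20
    ts_fold: float = 50.0
    n_planted_pairs: int = 5
    # Calibrated by power analysis (see docs/methods.md): with 8 tissues
    # Kendall tau moves in 1/28 steps and the null among ~400 competitor
    # genes reaches ~0.79, so a planted pair is recoverable by
    # construction only when its population tau ((2/pi)asin(rho)) and the
    # latent-to-noise spread keep expected inversions well below ~3.
    pair_latent_correlation: float = 0.999
    # expression model (TPM scale, natural-log dispersions)
    baseline_meanlog: float = math.log(50.0)
    baseline_sdlog: float = 1.0
    noise_sdlog: float = 0.3
    latent_sdlog: float = 2.0
    lib_size_range: tuple[float, float] = (5e5, 5e6)

    def __post_init__(self):
        if len(self.source_tags) != len(self.n_genes_per_source) or len(
            self.source_tags
        ) != len(self.overlap_fractions):
            raise ValueError("per-source field lengths disagree")
        if any(not (0.0 <= f <= 1.0) for f in self.overlap_fractions):
            raise ValueError("overlap fractions must be in [0, 1]")
        if self.ts_fold <= 1:
            raise ValueError("ts_fold must be > 1")

    @property
    def tissues(self) -> list[str]:
        return [f"tissue{i + 1:02d}" for i in range(self.n_tissues)]

    @property
    def projects(self) -> list[str]:
        return [f"P{i + 1}" for i in range(self.n_projects)]


@dataclass
class FixtureTruth:
    """Planted ground truth recorded by the generator."""

    rejected_by_source: dict[str, list[str]] = field(default_factory=dict)
    clone_of: dict[str, str] = field(default_factory=dict)
    planted_ts: list[dict] = field(default_factory=list)  # gene_id, tissue, fold
    planted_pairs: list[dict] = field(default_factory=list)
    uniform_genes: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def _random_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    start: int,
    strand: str,
    biotype_class: str,
    source: str,
) -> GeneModel:
    """One gene with 1-2 transcripts of 1-4 exons starting at ``start``."""
    n_exons = 1 if biotype_class in ("mirna", "smallrna") else int(rng.integers(1, 5))
    exon_lens = rng.integers(100, 500, size=n_exons)
    intron_lens = rng.integers(200, 2000, size=max(0, n_exons - 1))
    exons = []
    pos = start
    for i in range(n_exons):
        exons.append(ExonInterval(chrom, pos, pos + int(exon_lens[i]), strand))
        if i < n_exons - 1:
            pos += int(exon_lens[i]) + int(intron_lens[i])
    transcripts = [
        TranscriptModel(f"{gene_id}.t1", gene_id, exons)
    ]
    if n_exons >= 2 and rng.random() < 0.4:  # second isoform drops one exon
        drop = int(rng.integers(0, n_exons))
        kept = [e for i, e in enumerate(exons) if i != drop] or exons[:1]
        transcripts.append(TranscriptModel(f"{gene_id}.t2", gene_id, kept))
    return GeneModel(
        gene_id=gene_id,
        gene_name=gene_id.upper(),
        biotype_class=biotype_class,
        source=source,
        transcripts=transcripts,
    )


def _biotype_draw(rng: np.random.Generator) -> str:
    return str(
        rng.choice(
            ["pcg", "lnc", "mirna", "smallrna"], p=[0.40, 0.40, 0.10, 0.10]
        )
    )


def _plant_pair(
    rng: np.random.Generator,
    idx: int,
    config: str,
    distance: int,
    chrom: str,
    start: int,
    tag: str,
) -> tuple[GeneModel, GeneModel, dict, int]:
    """Build one pair with exact geometry; returns genes, truth, end coord."""
    a_id, b_id = f"{tag}_pairL{idx}", f"{tag}_pairP{idx}"
    if config == "divergent":
        # '-' lnc left, '+' pcg right, TSS-to-TSS = distance
        lnc = GeneModel(
            a_id, biotype_class="lnc", source=tag, gene_name=a_id.upper(),
            transcripts=[TranscriptModel(
                f"{a_id}.t1", a_id,
                [ExonInterval(chrom, start, start + 800, "-")],
            )],
        )
        tss_b = (start + 800) + distance
        pcg = GeneModel(
            b_id, biotype_class="pcg", source=tag, gene_name=b_id.upper(),
            transcripts=[TranscriptModel(
                f"{b_id}.t1", b_id,
                [ExonInterval(chrom, tss_b, tss_b + 1200, "+")],
            )],
        )
        expected = dict(category="intergenic", orientation="divergent",
                        distance_bp=distance, subclass_label="lncgDIVinter")
        end = tss_b + 1200
    elif config == "convergent":
        # '+' lnc left, '-' pcg right, tails facing
        lnc = GeneModel(
            a_id, biotype_class="lnc", source=tag, gene_name=a_id.upper(),
            transcripts=[TranscriptModel(
                f"{a_id}.t1", a_id,
                [ExonInterval(chrom, start, start + 800, "+")],
            )],
        )
        tss_b = start + distance  # '-' TSS = right end of partner
        pcg = GeneModel(
            b_id, biotype_class="pcg", source=tag, gene_name=b_id.upper(),
            transcripts=[TranscriptModel(
                f"{b_id}.t1", b_id,
                [ExonInterval(chrom, tss_b - 1200, tss_b, "-")],
            )],
        )
        expected = dict(category="intergenic", orientation="convergent",
                        distance_bp=distance, subclass_label="lncgCONVinter")
        end = tss_b
    elif config == "sense":
        lnc = GeneModel(
            a_id, biotype_class="lnc", source=tag, gene_name=a_id.upper(),
            transcripts=[TranscriptModel(
                f"{a_id}.t1", a_id,
                [ExonInterval(chrom, start, start + 800, "+")],
            )],
        )
        tss_b = start + distance
        pcg = GeneModel(
            b_id, biotype_class="pcg", source=tag, gene_name=b_id.upper(),
            transcripts=[TranscriptModel(
                f"{b_id}.t1", b_id,
                [ExonInterval(chrom, tss_b, tss_b + 1200, "+")],
            )],
        )
        expected = dict(category="intergenic", orientation="sense",
                        distance_bp=distance, subclass_label="lncgSSinter")
        end = tss_b + 1200
    elif config == "nested_intronic":
        # lnc inside the intron of a 2-exon pcg, same strand
        pcg = GeneModel(
            b_id, biotype_class="pcg", source=tag, gene_name=b_id.upper(),
            transcripts=[TranscriptModel(
                f"{b_id}.t1", b_id,
                [
                    ExonInterval(chrom, start, start + 300, "+"),
                    ExonInterval(chrom, start + 4300, start + 4600, "+"),
                ],
            )],
        )
        lnc = GeneModel(
            a_id, biotype_class="lnc", source=tag, gene_name=a_id.upper(),
            transcripts=[TranscriptModel(
                f"{a_id}.t1", a_id,
                [ExonInterval(chrom, start + 1000, start + 1600, "+")],
            )],
        )
        expected = dict(category="genic", orientation="sense",
                        distance_bp=0, subclass_label="lncgSSinNest")
        end = start + 4600
    else:
        raise ValueError(f"unknown pair configuration {config!r}")
    truth = dict(
        gene_a=a_id, gene_b=b_id, configuration=config,
        distance=distance, expected=expected,
    )
    return lnc, pcg, truth, end


def simulate_annotations(
    spec: FixtureSpec, rng: Optional[np.random.Generator] = None
) -> tuple[list[Annotation], FixtureTruth]:
    """Generate the annotation sources and their planted merge truth.

    Source 1 carries the planted pairs and non-overlapping background
    genes; each later source mixes clones (one exon jittered inside a
    random source-1 gene's exon, same strand: guaranteed >= 1 bp overlap)
    with novel genes placed in a territory disjoint from every other
    source.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    truth = FixtureTruth()
    chroms = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    annotations: list[Annotation] = []

    # --- source 1 ---
    tag1 = spec.source_tags[0]
    src1 = Annotation(tag1)
    cursors = {c: 10_000 for c in chroms}
    pair_chrom = chroms[0]
    for i in range(spec.n_planted_pairs):
        config, distance = DEFAULT_PAIR_CONFIGS[i % len(DEFAULT_PAIR_CONFIGS)]
        a, b, ptruth, end = _plant_pair(
            rng, i, config, distance, pair_chrom, cursors[pair_chrom], tag1
        )
        src1.add_gene(a)
        src1.add_gene(b)
        truth.planted_pairs.append(ptruth)
        cursors[pair_chrom] = end + 150_000  # outside the pairing window

    n_background = spec.n_genes_per_source[0] - 2 * spec.n_planted_pairs
    for i in range(n_background):
        chrom = chroms[i % len(chroms)]
        gid = f"{tag1}_g{i:04d}"
        gene = _random_gene(
            rng, gid, chrom, cursors[chrom],
            strand="+" if rng.random() < 0.5 else "-",
            biotype_class=_biotype_draw(rng), source=tag1,
        )
        src1.add_gene(gene)
        cursors[chrom] = gene.end + int(rng.integers(2_000, 20_000))
    annotations.append(src1)

    src1_genes = list(src1)

    # --- later sources: clones + novel genes in disjoint territory ---
    for s_idx in range(1, len(spec.source_tags)):
        tag = spec.source_tags[s_idx]
        n_total = spec.n_genes_per_source[s_idx]
        n_clones = int(round(spec.overlap_fractions[s_idx] * n_total))
        ann = Annotation(tag)
        rejected: list[str] = []
        origin_idx = rng.choice(len(src1_genes), size=n_clones, replace=False)
        for j, oi in enumerate(sorted(origin_idx)):
            origin = src1_genes[int(oi)]
            exon = origin.transcripts[0].exons[0]
            width = len(exon)
            shift = int(rng.integers(-width + 1, width))  # keeps >= 1 bp shared
            start = max(0, exon.start + shift)
            gid = f"{tag}_c{j:04d}"
            ann.add_gene(
                GeneModel(
                    gid, biotype_class=origin.biotype_class, source=tag,
                    gene_name=gid.upper(),
                    transcripts=[TranscriptModel(
                        f"{gid}.t1", gid,
                        [ExonInterval(exon.chrom, start, start + width, exon.strand)],
                    )],
                )
            )
            rejected.append(gid)
            truth.clone_of[gid] = origin.gene_id
        # novel genes: territory far beyond everything placed so far
        base = 10_000_000 * (s_idx + 1)
        novel_cursors = {c: base for c in chroms}
        for j in range(n_total - n_clones):
            chrom = chroms[j % len(chroms)]
            gid = f"{tag}_g{j:04d}"
            gene = _random_gene(
                rng, gid, chrom, novel_cursors[chrom],
                strand="+" if rng.random() < 0.5 else "-",
                biotype_class=_biotype_draw(rng), source=tag,
            )
            ann.add_gene(gene)
            novel_cursors[chrom] = gene.end + int(rng.integers(2_000, 20_000))
        truth.rejected_by_source[tag] = rejected
        annotations.append(ann)

    return annotations, truth


def simulate_expression(
    spec: FixtureSpec,
    annotation: Annotation,
    truth: Optional[FixtureTruth] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[SampleMeta], FixtureTruth]:
    """Counts, TPM and metadata for every gene of ``annotation``.

    Per-gene baselines are log-normal; planted TS genes are multiplied by
    ``ts_fold`` in one tissue; planted pairs share a per-tissue latent
    factor at the stated correlation; counts are multinomial draws given
    the TPM composition and a log-uniform library size.
    """
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    truth = truth if truth is not None else FixtureTruth()
    genes = sorted(annotation.genes)
    gindex = {g: i for i, g in enumerate(genes)}
    tissues = spec.tissues
    n_g, n_t = len(genes), len(tissues)

    baseline = rng.lognormal(spec.baseline_meanlog, spec.baseline_sdlog, size=n_g)
    # expected TPM-scale expression per gene per tissue
    mu = np.tile(baseline[:, None], (1, n_t))

    # plant TS genes among background genes not already in a pair
    paired = {p["gene_a"] for p in truth.planted_pairs} | {
        p["gene_b"] for p in truth.planted_pairs
    }
    eligible = [g for g in genes if g not in paired]
    ts_ids = [
        eligible[int(i)]
        for i in rng.choice(len(eligible), size=min(spec.n_planted_ts, len(eligible)),
                            replace=False)
    ]
    truth.planted_ts = []
    for k, gid in enumerate(ts_ids):
        tissue = tissues[k % n_t]
        mu[gindex[gid], tissues.index(tissue)] *= spec.ts_fold
        truth.planted_ts.append(
            {"gene_id": gid, "tissue": tissue, "fold": spec.ts_fold}
        )
    truth.uniform_genes = [g for g in genes if g not in {t["gene_id"] for t in truth.planted_ts}
                           and g not in paired]

    # Planted pairs: shared per-tissue latent factor.  Pair genes emulate
    # well-expressed co-expressed loci, so their baselines are pinned in
    # the upper expression range; near the detection floor, counting noise
    # would swamp the latent factor and the planted correlation would not
    # actually be present in the emitted data.
    rho = spec.pair_latent_correlation
    pair_baseline = math.exp(spec.baseline_meanlog + spec.baseline_sdlog)
    for p in truth.planted_pairs:
        if p["gene_a"] not in gindex or p["gene_b"] not in gindex:
            continue  # pair gene rejected at merge (not expected by default)
        mu[gindex[p["gene_a"]]] = pair_baseline
        mu[gindex[p["gene_b"]]] = pair_baseline
        f = rng.normal(0.0, spec.latent_sdlog, size=n_t)
        g_ind = rng.normal(0.0, spec.latent_sdlog, size=n_t)
        mu[gindex[p["gene_a"]]] *= np.exp(f)
        mu[gindex[p["gene_b"]]] *= np.exp(
            rho * f + math.sqrt(max(0.0, 1 - rho**2)) * g_ind
        )
        p["latent_correlation"] = rho

    samples: list[SampleMeta] = []
    lengths = {g: exonic_bases(annotation.genes[g]) for g in genes}
    len_arr = np.array([lengths[g] for g in genes], dtype=float)
    count_cols = {}
    lo, hi = spec.lib_size_range
    for project in spec.projects:
        for tissue in tissues:
            t_i = tissues.index(tissue)
            for r in range(spec.samples_per_tissue_project):
                sid = f"{project}_{tissue}_s{r + 1}"
                samples.append(
                    SampleMeta(
                        sid, project=project, tissue=tissue,
                        sex="F" if len(samples) % 2 == 0 else "M",
                    )
                )
                expr = mu[:, t_i] * rng.lognormal(0.0, spec.noise_sdlog, size=n_g)
                weights = expr * len_arr  # read probability ~ abundance x length
                p_vec = weights / weights.sum()
                lib = int(np.exp(rng.uniform(math.log(lo), math.log(hi))))
                count_cols[sid] = rng.multinomial(lib, p_vec)

    counts = pd.DataFrame(count_cols, index=genes)
    tpm = tpm_normalize(counts, lengths)
    return counts, tpm, samples, truth
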