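import numpy as np
import pandas as pd
import pytest

from atlaskit import (
    Annotation,
    ExonInterval,
    GeneModel,
    MergePolicy,
    TranscriptModel,
    merge_annotations,
    tissue_medians,
)
from atlaskit.simulate import FixtureSpec, simulate_annotations, simulate_expression


def make_gene(
    gene_id,
    exons,
    strand="+",
    chrom="chr1",
    biotype_class="pcg",
    source="test",
    gene_name=None,
):
    """One single-transcript gene from a list of (start, end) tuples."""
    return GeneModel(
        gene_id=gene_id,
        gene_name=gene_name,
        biotype_class=biotype_class,
        source=source,
        transcripts=[
            TranscriptModel(
                f"{gene_id}.t1",
                gene_id,
                [ExonInterval(chrom, s, e, strand) for s, e in exons],
            )
        ],
    )


@pytest.fixture(scope="session")
def default_spec():
    return FixtureSpec(seed=20240816)


@pytest.fixture(scope="session")
def default_fixture(default_spec):
    """The standard synthetic atlas: sources, merged atlas, expression, truth."""
    annotations, truth = simulate_annotations(default_spec)
    atlas = merge_annotations(
        annotations, MergePolicy(source_order=default_spec.source_tags)
    )
    counts, tpm, samples, truth = simulate_expression(
        default_spec, atlas.annotation, truth
    )
    profiles = tissue_medians(tpm, samples)
    return {
        "spec": default_spec,
        "annotations": annotations,
        "atlas": atlas,
        "counts": counts,
        "tpm": tpm,
        "samples": samples,
        "truth": truth,
        "profiles": profiles,
    }


def brute_force_shared_bp(a: GeneModel, b: GeneModel) -> int:
    """Per-base set intersection of two genes' exon unions (oracle)."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return 0
    bases_a = set()
    for t in a.transcripts:
        for e in t.exons:
            bases_a.update(range(e.start, e.end))
    bases_b = set()
    for t in b.transcripts:
        for e in t.exons:
            bases_b.update(range(e.start, e.end))
    return len(bases_a & bases_b)


def kendall_brute(x, y):
    """O(n^2) tau-b oracle: explicit concordant/discordant/tie counting."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    s = dx[iu] * dy[iu]
    numer = s.sum()
    n0 = n * (n - 1) / 2
    n1 = np.sum(dx[iu] == 0)
    n2 = np.sum(dy[iu] == 0)
    denom = np.sqrt((n0 - n1) * (n0 - n2))
    if denom == 0:
        return None
    return numer / denom
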