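"""Gene, transcript and exon models plus GTF input/output.

Coordinate convention: everything in memory is 0-based half-open
(``start`` inclusive, ``end`` exclusive), the convention that makes
overlap and distance arithmetic unambiguous.  GTF files use 1-based
fully-closed coordinates; :func:`parse_gtf` and :func:`write_gtf`
convert at the boundary and nowhere else.

Biotypes are collapsed into a closed five-class vocabulary (``pcg``,
``lnc``, ``mirna``, ``smallrna``, ``other``) through an explicit,
user-overridable mapping; :data:`DEFAULT_BIOTYPE_MAP` covers the
RefSeq/Ensembl raw labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional

from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

BIOTYPE_CLASSES = ("pcg", "lnc", "mirna", "smallrna", "other")

#: Raw GTF biotype label -> coarse class.  Small RNAs group snoRNA, snRNA,
#: sRNA, tRNA, rRNA and scaRNA.
DEFAULT_BIOTYPE_MAP: dict[str, str] = {
    "protein_coding": "pcg",
    "lncRNA": "lnc",
    "lincRNA": "lnc",
    "lnc_RNA": "lnc",
    "antisense": "lnc",
    "miRNA": "mirna",
    "snoRNA": "smallrna",
    "snRNA": "smallrna",
    "sRNA": "smallrna",
    "tRNA": "smallrna",
    "rRNA": "smallrna",
    "scaRNA": "smallrna",
}


class GtfParseError(ValueError):
    """A malformed GTF line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ValidationError(ValueError):
    """A structurally invalid feature (e.g. transcript with no exons)."""


@dataclass(frozen=True, order=True)
class ExonInterval:
    """A stranded exon interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("exon chrom must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValidationError(
                f"exon start must be < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class TranscriptModel:
    """One transcript: a sorted run of non-overlapping exons on one strand.

    The TSS is the 5' end: the minimal exon start on '+', the maximal
    exon end on '-'.
    """

    transcript_id: str
    gene_id: str
    exons: list[ExonInterval]

    def __post_init__(self):
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id} has zero exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"transcript {self.transcript_id} mixes chrom/strand: "
                f"{chroms} / {strands}"
            )
        self.exons = _merge_sorted(self.exons)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


def _merge_sorted(exons: Iterable[ExonInterval]) -> list[ExonInterval]:
    """Sort exons and merge any that overlap or duplicate."""
    out: list[ExonInterval] = []
    for e in sorted(exons, key=lambda x: (x.start, x.end)):
        if out and e.start < out[-1].end:
            last = out[-1]
            if e.end > last.end:
                out[-1] = ExonInterval(last.chrom, last.start, e.end, last.strand)
        else:
            out.append(e)
    return out


@dataclass
class GeneModel:
    """A gene: one or more transcripts sharing chrom and strand."""

    gene_id: str
    biotype_class: str
    source: str
    transcripts: list[TranscriptModel]
    gene_name: Optional[str] = None

    def __post_init__(self):
        if not self.transcripts:
            raise ValidationError(f"gene {self.gene_id} has zero transcripts")
        if self.biotype_class not in BIOTYPE_CLASSES:
            raise ValidationError(
                f"gene {self.gene_id}: biotype_class {self.biotype_class!r} "
                f"not in {BIOTYPE_CLASSES}"
            )
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"gene {self.gene_id} mixes chrom/strand: {chroms} / {strands}"
            )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def span(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)

    @property
    def tss_set(self) -> set[int]:
        return {t.tss for t in self.transcripts}

    def exon_union(self) -> list[tuple[int, int]]:
        """Merged (start, end) intervals of all exons across transcripts."""
        ivs = sorted(
            (e.start, e.end) for t in self.transcripts for e in t.exons
        )
        out: list[tuple[int, int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                if e > out[-1][1]:
                    out[-1] = (out[-1][0], e)
            else:
                out.append((s, e))
        return out


def exonic_bases(gene: GeneModel) -> int:
    """Size in bp of the union of all exon intervals across transcripts."""
    return sum(e - s for s, e in gene.exon_union())


class Annotation:
    """A set of gene models from one source, with a stranded exon index.

    The index maps (chrom, strand) to an :class:`IntervalTree` of exon
    intervals whose payload is the owning gene_id, supporting overlap
    queries in O(log n + k).
    """

    def __init__(self, source_tag: str, genes: Iterable[GeneModel] = ()):
        self.source_tag = source_tag
        self.genes: dict[str, GeneModel] = {}
        self._index: dict[tuple[str, str], IntervalTree] = {}
        for g in genes:
            self.add_gene(g)

    def add_gene(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise ValidationError(
                f"duplicate gene_id {gene.gene_id!r} in {self.source_tag}"
            )
        self.genes[gene.gene_id] = gene
        tree = self._index.setdefault((gene.chrom, gene.strand), IntervalTree())
        for s, e in gene.exon_union():
            tree.addi(s, e, gene.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def query_exons(self, chrom: str, start: int, end: int, strand: str) -> set[str]:
        """Gene ids with at least one exonic base in [start, end) on ``strand``."""
        tree = self._index.get((chrom, strand))
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}

    def genes_by_class(self, biotype_class: str) -> list[GeneModel]:
        return [g for g in self if g.biotype_class == biotype_class]


def parse_gtf(
    path,
    source_tag: str,
    biotype_map: Mapping[str, str] | None = None,
) -> Annotation:
    """Parse a GTF file into an :class:`Annotation`.

    Genes are assembled from exon features (``gene_id``/``transcript_id``
    attributes are required on exons); explicit ``gene`` and ``transcript``
    features contribute biotype and name attributes but genes lacking them
    are reconstructed as envelopes of their transcripts.  Raw biotypes are
    looked up in ``biotype_map`` (default :data:`DEFAULT_BIOTYPE_MAP`);
    unmapped labels fall back to ``'other'`` with a logged warning.
    """
    if biotype_map is None:
        biotype_map = DEFAULT_BIOTYPE_MAP

    exons_by_tx: dict[str, list[ExonInterval]] = {}
    tx_gene: dict[str, str] = {}
    gene_attrs: dict[str, dict] = {}
    gene_order: list[str] = []
    reconstructed: set[str] = set()

    def note_gene(gid: str):
        if gid not in gene_attrs:
            gene_attrs[gid] = {}
            gene_order.append(gid)

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"expected 9 tab-separated fields, got {len(fields)}", lineno
                )
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # gffutils raises assorted types
                raise GtfParseError(str(exc), lineno) from exc
            ftype = feat.featuretype
            if ftype not in ("gene", "transcript", "exon"):
                continue
            attrs = feat.attributes
            gid_list = attrs.get("gene_id")
            if not gid_list:
                raise GtfParseError("missing gene_id attribute", lineno)
            gid = _gtf_attr_unescape(gid_list[0])
            note_gene(gid)
            raw_biotype = None
            for key in ("gene_biotype", "gene_type", "biotype"):
                if key in attrs:
                    raw_biotype = attrs[key][0]
                    break
            if raw_biotype is not None:
                gene_attrs[gid].setdefault("raw_biotype", raw_biotype)
            if "gene_name" in attrs:
                gene_attrs[gid].setdefault(
                    "gene_name", _gtf_attr_unescape(attrs["gene_name"][0])
                )
            if ftype == "gene":
                gene_attrs[gid]["explicit"] = True
                continue
            tid_list = attrs.get("transcript_id")
            if not tid_list:
                raise GtfParseError(f"missing transcript_id on {ftype}", lineno)
            tid = _gtf_attr_unescape(tid_list[0])
            tx_gene[tid] = gid
            if ftype == "transcript":
                exons_by_tx.setdefault(tid, [])
                continue
            try:
                start0 = feat.start - 1  # GTF is 1-based inclusive
                exon = ExonInterval(feat.seqid, start0, feat.end, feat.strand)
            except ValidationError as exc:
                raise GtfParseError(str(exc), lineno) from exc
            exons_by_tx.setdefault(tid, []).append(exon)

    tx_by_gene: dict[str, list[TranscriptModel]] = {}
    for tid, exons in exons_by_tx.items():
        gid = tx_gene[tid]
        if not exons:
            raise ValidationError(f"transcript {tid} has zero exons")
        tx_by_gene.setdefault(gid, []).append(
            TranscriptModel(transcript_id=tid, gene_id=gid, exons=exons)
        )

    ann = Annotation(source_tag)
    unmapped: set[str] = set()
    for gid in gene_order:
        transcripts = tx_by_gene.get(gid)
        if not transcripts:
            raise ValidationError(f"gene {gid} has zero exon-bearing transcripts")
        transcripts.sort(key=lambda t: t.transcript_id)
        attrs = gene_attrs[gid]
        raw = attrs.get("raw_biotype")
        if raw is None:
            biotype_class = "other"
        elif raw in biotype_map:
            biotype_class = biotype_map[raw]
        elif raw in BIOTYPE_CLASSES:
            biotype_class = raw
        else:
            unmapped.add(raw)
            biotype_class = "other"
        if not attrs.get("explicit"):
            reconstructed.add(gid)
        ann.add_gene(
            GeneModel(
                gene_id=gid,
                gene_name=attrs.get("gene_name"),
                biotype_class=biotype_class,
                source=source_tag,
                transcripts=transcripts,
            )
        )
    if unmapped:
        logger.warning(
            "%s: %d unmapped biotype label(s) -> 'other': %s",
            source_tag, len(unmapped), ", ".join(sorted(unmapped)),
        )
    if reconstructed:
        logger.info(
            "%s: %d gene(s) reconstructed from transcripts (no gene feature)",
            source_tag, len(reconstructed),
        )
    ann.reconstructed_gene_ids = reconstructed  # provenance of envelope genes
    return ann


# Inverse of the default mapping, used when writing: one representative
# raw label per class so a round-trip preserves the class.
_CLASS_TO_RAW = {
    "pcg": "protein_coding",
    "lnc": "lncRNA",
    "mirna": "miRNA",
    "smallrna": "snoRNA",
    "other": "other",
}


# GTF has no standard escaping for reserved characters inside quoted
# attribute values; we apply the GFF3 percent-encoding convention to the
# characters that break attribute tokenization, and decode on parse.
_ATTR_ENCODE = {"%": "%25", ";": "%3B", '"': "%22", "\t": "%09", "\n": "%0A"}


def _gtf_attr_escape(value: str) -> str:
    for raw, enc in _ATTR_ENCODE.items():
        value = value.replace(raw, enc)
    return value


def _gtf_attr_unescape(value: str) -> str:
    for raw, enc in reversed(_ATTR_ENCODE.items()):
        value = value.replace(enc, raw)
    return value


def write_gtf(annotation: Annotation, path) -> None:
    """Write an annotation as GTF (1-based inclusive coordinates).

    Round-trip guarantee: ``parse_gtf(write_gtf(A))`` reproduces A's
    genes, transcripts, exons, strands and biotype classes exactly.
    """
    with open(path, "w") as fh:
        fh.write(f"#!atlaskit annotation source={annotation.source_tag}\n")
        for gene in sorted(
            annotation, key=lambda g: (g.chrom, g.start, g.gene_id)
        ):
            raw_biotype = _CLASS_TO_RAW[gene.biotype_class]
            base = (
                f'gene_id "{_gtf_attr_escape(gene.gene_id)}"; '
                f'gene_biotype "{raw_biotype}";'
            )
            if gene.gene_name is not None:
                base += f' gene_name "{_gtf_attr_escape(gene.gene_name)}";'
            fh.write(
                "\t".join(
                    [
                        gene.chrom,
                        annotation.source_tag,
                        "gene",
                        str(gene.start + 1),
                        str(gene.end),
                        ".",
                        gene.strand,
                        ".",
                        base,
                    ]
                )
                + "\n"
            )
            for tx in gene.transcripts:
                tattrs = (
                    f'gene_id "{_gtf_attr_escape(gene.gene_id)}"; '
                    f'transcript_id "{_gtf_attr_escape(tx.transcript_id)}"; '
                    f'gene_biotype "{raw_biotype}";'
                )
                fh.write(
                    "\t".join(
                        [
                            gene.chrom,
                            annotation.source_tag,
                            "transcript",
                            str(tx.start + 1),
                            str(tx.end),
                            ".",
                            gene.strand,
                            ".",
                            tattrs,
                        ]
                    )
                    + "\n"
                )
                for exon in tx.exons:
                    fh.write(
                        "\t".join(
                            [
                                exon.chrom,
                                annotation.source_tag,
                                "exon",
                                str(exon.start + 1),
                                str(exon.end),
                                ".",
                                exon.strand,
                                ".",
                                tattrs,
                            ]
                        )
                        + "\n"
                    )
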