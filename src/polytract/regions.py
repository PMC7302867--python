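"""Genomic region assignment of polytracts from an Ensembl-dialect GTF.

Each polytract is assigned to exactly one of seven region categories:

    exonic_splicing > UTR5 > UTR3 > ncRNA > intronic > up_down_stream > intergenic

resolved by that fixed precedence when a tract touches several.
``exonic_splicing`` means overlap with a protein-coding CDS or with a
splice-window around an internal intron/exon boundary of a protein-coding
transcript; UTR5/UTR3 come from the explicit GTF UTR features; ``ncRNA`` is
overlap with an exon of a non-protein-coding gene; ``intronic`` is any
position within a gene span not claimed above; ``up_down_stream`` covers a
configurable window (default 1 kb) beyond either end of a gene span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

from .scanner import PolytractRecord

__all__ = [
    "GeneModel",
    "REGION_CATEGORIES",
    "load_gene_models",
    "RegionIndex",
    "assign_region",
    "region_distribution",
]

REGION_CATEGORIES = (
    "exonic_splicing",
    "UTR5",
    "UTR3",
    "ncRNA",
    "intronic",
    "up_down_stream",
    "intergenic",
)

_UTR5_TYPES = {"five_prime_utr", "5UTR"}
_UTR3_TYPES = {"three_prime_utr", "3UTR"}


@dataclass
class GeneModel:
    """Intervals of one gene, 0-based half-open on its chromosome."""

    gene_id: str
    chrom: str
    gene_type: str
    strand: str
    span: tuple[int, int]
    transcripts: dict[str, tuple[int, int]] = field(default_factory=dict)
    exons: set[tuple[int, int]] = field(default_factory=set)
    cds: set[tuple[int, int]] = field(default_factory=set)
    utr5: set[tuple[int, int]] = field(default_factory=set)
    utr3: set[tuple[int, int]] = field(default_factory=set)
    #: exon intervals grouped per transcript, for junction derivation
    transcript_exons: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def is_coding(self) -> bool:
        return self.gene_type == "protein_coding"


def _attr(feature, *names: str) -> str | None:
    for name in names:
        if name in feature.attributes:
            return feature.attributes[name][0]
    return None


def load_gene_models(gtf_path: str) -> list[GeneModel]:
    """Parse an Ensembl-dialect GTF into gene models.

    Malformed lines are skipped with a warning; records without a gene_id
    are rejected.  Exon intervals are deduplicated across transcripts
    (unique intervals kept).  Genes for which only a ``gene`` line exists
    get an empty exon set.
    """
    models: dict[str, GeneModel] = {}
    skipped = 0
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                f = feature_from_line(line)
            except Exception:
                skipped += 1
                warnings.warn(f"{gtf_path}:{lineno}: malformed GTF line skipped")
                continue
            gene_id = _attr(f, "gene_id")
            if gene_id is None:
                skipped += 1
                warnings.warn(f"{gtf_path}:{lineno}: record without gene_id rejected")
                continue
            start, end = f.start - 1, f.end  # GTF is 1-based inclusive
            model = models.get(gene_id)
            if model is None:
                gene_type = _attr(f, "gene_biotype", "gene_type") or "unknown"
                model = GeneModel(
                    gene_id=gene_id,
                    chrom=f.seqid,
                    gene_type=gene_type,
                    strand=f.strand if f.strand in "+-" else "+",
                    span=(start, end),
                )
                models[gene_id] = model
            model.span = (min(model.span[0], start), max(model.span[1], end))
            ftype = f.featuretype
            if ftype == "gene":
                gt = _attr(f, "gene_biotype", "gene_type")
                if gt:
                    model.gene_type = gt
            elif ftype == "transcript":
                tid = _attr(f, "transcript_id")
                if tid:
                    model.transcripts[tid] = (start, end)
            elif ftype == "exon":
                model.exons.add((start, end))
                tid = _attr(f, "transcript_id")
                if tid:
                    model.transcript_exons.setdefault(tid, []).append((start, end))
            elif ftype == "CDS":
                model.cds.add((start, end))
            elif ftype in _UTR5_TYPES:
                model.utr5.add((start, end))
            elif ftype in _UTR3_TYPES:
                model.utr3.add((start, end))
    for model in models.values():
        if not model.exons:
            warnings.warn(f"gene {model.gene_id} has no exon records")
    return sorted(models.values(), key=lambda m: (m.chrom, m.span))


class RegionIndex:
    """Interval trees over a gene-model set for region category lookup."""

    def __init__(
        self,
        models: Sequence[GeneModel],
        updown_kb: float = 1.0,
        splice_window: int = 2,
    ) -> None:
        self.updown = int(round(updown_kb * 1000))
        self.splice_window = splice_window
        trees: dict[str, dict[str, IntervalTree]] = {}

        def add(kind: str, chrom: str, start: int, end: int) -> None:
            if end <= start:
                return
            trees.setdefault(chrom, {}).setdefault(kind, IntervalTree()).addi(start, end)

        for m in models:
            for s, e in sorted(m.exons):
                if m.is_coding:
                    if not m.cds:
                        # coding gene annotated without CDS lines: whole exon
                        add("exonic", m.chrom, s, e)
                else:
                    add("ncrna", m.chrom, s, e)
            for s, e in m.cds:
                add("exonic", m.chrom, s, e)
            for s, e in m.utr5:
                add("utr5", m.chrom, s, e)
            for s, e in m.utr3:
                add("utr3", m.chrom, s, e)
            if m.is_coding:
                w = self.splice_window
                exon_sets = m.transcript_exons.values() or [sorted(m.exons)]
                for exons in exon_sets:
                    exons = sorted(exons)
                    if len(exons) < 2:
                        continue
                    # internal boundaries only: each exon end but the last,
                    # each exon start but the first
                    for s, e in exons[:-1]:
                        add("exonic", m.chrom, e - w, e + w)
                    for s, e in exons[1:]:
                        add("exonic", m.chrom, s - w, s + w)
            add("gene", m.chrom, *m.span)
            add(
                "updown",
                m.chrom,
                max(0, m.span[0] - self.updown),
                m.span[1] + self.updown,
            )
        self._trees = trees

    def _hits(self, kind: str, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom, {}).get(kind)
        return bool(tree is not None and tree.overlap(start, end))

    def category(self, chrom: str, start: int, end: int) -> str:
        if self._hits("exonic", chrom, start, end):
            return "exonic_splicing"
        if self._hits("utr5", chrom, start, end):
            return "UTR5"
        if self._hits("utr3", chrom, start, end):
            return "UTR3"
        if self._hits("ncrna", chrom, start, end):
            return "ncRNA"
        if self._hits("gene", chrom, start, end):
            return "intronic"
        if self.updown > 0 and self._hits("updown", chrom, start, end):
            return "up_down_stream"
        return "intergenic"


def assign_region(
    interval: tuple[str, int, int],
    models: Sequence[GeneModel] | RegionIndex,
    updown_kb: float = 1.0,
    splice_window: int = 2,
) -> str:
    """Region category of one [start, end) interval under the fixed precedence."""
    index = (
        models
        if isinstance(models, RegionIndex)
        else RegionIndex(models, updown_kb=updown_kb, splice_window=splice_window)
    )
    chrom, start, end = interval
    return index.category(chrom, start, end)


def region_distribution(
    tracts: Iterable[PolytractRecord],
    models: Sequence[GeneModel] | RegionIndex,
    updown_kb: float = 1.0,
    splice_window: int = 2,
) -> pd.DataFrame:
    """Per-species counts and fractions over the seven region categories.

    Fractions sum to 1 within each species row.  Returns a DataFrame indexed
    by (clade, species) with one count column and one fraction column per
    category.
    """
    index = (
        models
        if isinstance(models, RegionIndex)
        else RegionIndex(models, updown_kb=updown_kb, splice_window=splice_window)
    )
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for t in tracts:
        row = counts.setdefault(
            (t.clade, t.species), {c: 0 for c in REGION_CATEGORIES}
        )
        row[index.category(t.chrom, t.start, t.end)] += 1
    rows = []
    keys = sorted(counts)
    for key in keys:
        row = counts[key]
        total = sum(row.values())
        entry: dict[str, float] = {}
        for c in REGION_CATEGORIES:
            entry[f"count_{c}"] = row[c]
            entry[f"frac_{c}"] = row[c] / total if total else 0.0
        rows.append(entry)
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(keys, names=["clade", "species"])
    )
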