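"""Readers and writers for the interchange formats.

BED is the single interchange format for tracts, hinges and interval
features (0-based half-open, as in BED); point features may also come as a
two-column chrom / 1-based-position TSV.  FASTA access goes through
pyfaidx.  Reports are TSV with a reproducibility header of ``#``-prefixed
key=value lines.
"""

from __future__ import annotations

import logging
import sys
from importlib.metadata import PackageNotFoundError, version
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyfaidx import Fasta

from .enrichment import EnrichmentResult, Interval
from .scanner import MOTIF_TO_SPECIES, HingeRecord, PolytractRecord, SPECIES_LABELS

logger = logging.getLogger("polytract")

__all__ = [
    "read_fasta",
    "read_bed",
    "read_points_tsv",
    "read_sizes_tsv",
    "write_sizes_tsv",
    "write_tracts_bed",
    "read_tracts_bed",
    "write_hinges_bed",
    "read_hinges_bed",
    "write_features_bed",
    "write_fasta",
    "write_report",
    "normalize_chrom",
    "filter_to_known_chroms",
]

try:
    _VERSION = version("polytract")
except PackageNotFoundError:  # pragma: no cover
    _VERSION = "unknown"

_SPECIES_BY_LABEL = {
    (clade, label) for clade in SPECIES_LABELS for label in SPECIES_LABELS[clade]
}
_UNIT_LEN = {"MNR": 1, "DNR": 2, "TNR": 3}


def normalize_chrom(name: str, chr_prefix: bool | None = None) -> str:
    """Optionally force ('chr1') or strip ('1') the chr prefix; None leaves as is."""
    if chr_prefix is None:
        return name
    has = name.startswith("chr")
    if chr_prefix and not has:
        return "chr" + name
    if not chr_prefix and has:
        return name[3:]
    return name


def read_fasta(
    path: str,
    names: Sequence[str] | None = None,
    chr_prefix: bool | None = None,
) -> dict[str, str]:
    """Sequences of a (plain or bgzipped) FASTA as uppercase-preserving strings.

    ``names`` restricts and orders the sequences; unknown requested names
    raise.  ``chr_prefix`` renames sequences on the fly.
    """
    fasta = Fasta(path, as_raw=True, sequence_always_upper=False)
    keys = list(fasta.keys())
    if names is not None:
        missing = [n for n in names if n not in fasta]
        if missing:
            raise KeyError(f"sequence(s) {missing} not in {path}")
        keys = list(names)
    return {normalize_chrom(k, chr_prefix): str(fasta[k][:]) for k in keys}


def write_fasta(sequences: Mapping[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _parse_lines(path: str):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_bed(
    path: str,
    chr_prefix: bool | None = None,
) -> list[tuple[str, int, int, str]]:
    """BED3+ records as (chrom, start, end, name); malformed lines are skipped
    with a logged warning and the run continues."""
    records = []
    skipped = 0
    for lineno, fields in _parse_lines(path):
        try:
            chrom = normalize_chrom(fields[0], chr_prefix)
            start, end = int(fields[1]), int(fields[2])
            if end < start:
                raise ValueError("end < start")
        except (IndexError, ValueError) as exc:
            skipped += 1
            logger.warning("%s:%d: malformed BED line skipped (%s)", path, lineno, exc)
            continue
        name = fields[3] if len(fields) > 3 else "."
        records.append((chrom, start, end, name))
    if skipped:
        logger.warning("%s: %d malformed line(s) skipped", path, skipped)
    return records


def read_points_tsv(
    path: str, chr_prefix: bool | None = None
) -> list[Interval]:
    """Two-column chrom / 1-based position TSV as 1-nt [pos-1, pos) intervals."""
    points: list[Interval] = []
    skipped = 0
    for lineno, fields in _parse_lines(path):
        try:
            chrom = normalize_chrom(fields[0], chr_prefix)
            pos = int(fields[1])
            if pos < 1:
                raise ValueError("position must be 1-based")
        except (IndexError, ValueError) as exc:
            skipped += 1
            logger.warning("%s:%d: malformed point skipped (%s)", path, lineno, exc)
            continue
        points.append((chrom, pos - 1, pos))
    if skipped:
        logger.warning("%s: %d malformed line(s) skipped", path, skipped)
    return points


def read_sizes_tsv(path: str, chr_prefix: bool | None = None) -> dict[str, int]:
    """Two-column chrom / length TSV (chrom.sizes style)."""
    sizes: dict[str, int] = {}
    for lineno, fields in _parse_lines(path):
        try:
            sizes[normalize_chrom(fields[0], chr_prefix)] = int(fields[1])
        except (IndexError, ValueError) as exc:
            logger.warning("%s:%d: malformed size line skipped (%s)", path, lineno, exc)
    return sizes


def write_sizes_tsv(seq_lengths: Mapping[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom in seq_lengths:
            fh.write(f"{chrom}\t{seq_lengths[chrom]}\n")


def write_tracts_bed(tracts: Iterable[PolytractRecord], path: str) -> None:
    """BED6: name = clade:species, score = length, strand = '.'."""
    with open(path, "w") as fh:
        for t in tracts:
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.clade}:{t.species}\t{t.length}\t.\n"
            )


def read_tracts_bed(path: str, chr_prefix: bool | None = None) -> list[PolytractRecord]:
    records = []
    for chrom, start, end, name in read_bed(path, chr_prefix):
        try:
            clade, species = name.split(":", 1)
            if (clade, species) not in _SPECIES_BY_LABEL:
                raise ValueError(f"unknown clade:species {name!r}")
        except ValueError as exc:
            logger.warning("%s: bad tract name %r skipped (%s)", path, name, exc)
            continue
        records.append(
            PolytractRecord(chrom, start, end, clade, species, _UNIT_LEN[clade])
        )
    records.sort(key=lambda r: (r.chrom, r.start, r.unit_len))
    return records


def write_hinges_bed(hinges: Iterable[HingeRecord], path: str) -> None:
    """BED4: 1-nt interval per hinge, name = left_species|right_species."""
    with open(path, "w") as fh:
        for h in hinges:
            fh.write(f"{h.chrom}\t{h.pos}\t{h.pos + 1}\t{h.left_species}|{h.right_species}\n")


def read_hinges_bed(path: str, chr_prefix: bool | None = None) -> list[HingeRecord]:
    hinges = []
    for chrom, start, end, name in read_bed(path, chr_prefix):
        if end - start != 1 or "|" not in name:
            logger.warning("%s: bad hinge record %r skipped", path, (chrom, start, end, name))
            continue
        left, right = name.split("|", 1)
        hinges.append(HingeRecord(chrom, start, left, right))
    hinges.sort()
    return hinges


def write_features_bed(features: Iterable[Interval], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in features:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def filter_to_known_chroms(
    features: Sequence[Interval], seq_lengths: Mapping[str, int]
) -> tuple[list[Interval], int]:
    """Drop features on unknown chromosomes (skip + warn, count reported)."""
    kept = [f for f in features if f[0] in seq_lengths]
    dropped = len(features) - len(kept)
    if dropped:
        logger.warning("%d feature(s) on unknown chromosome(s) skipped", dropped)
    return kept, dropped


_REPORT_COLUMNS = [
    "feature",
    "subset",
    "mode",
    "direction",
    "k",
    "M",
    "n",
    "N",
    "p",
    "RR",
    "ci_low",
    "ci_high",
    "significant",
]


def write_report(
    results: Sequence[EnrichmentResult],
    path: str,
    config: Mapping[str, object] | None = None,
) -> None:
    """Deterministic TSV report with a reproducibility header.

    Column order is fixed; floats are written at %.6g.  The header records
    the package version and every config key (including seeds) so a run can
    be reproduced from its report alone.
    """
    rows = [
        {col: getattr(r, col) for col in _REPORT_COLUMNS} for r in results
    ]
    df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"# polytract_version={_VERSION}\n")
        for key in sorted(config or {}):
            fh.write(f"# {key}={config[key]}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def setup_logging(level: str = "INFO") -> None:
    """Structured logging to stderr."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())
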