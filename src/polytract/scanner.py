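"""Detection and canonicalization of perfect very short tandem repeats.

A *polytract* is a maximal perfect run of a 1-, 2- or 3-nt motif
(mono-/di-/tri-nucleotide repeat; MNR/DNR/TNR clades), possibly ending in an
incomplete terminal unit.  The minimum size is six repeated units for an MNR
and three units for a DNR or TNR, i.e. 6/6/9 nt.  Runs are perfect matches
only: a single mismatching base ends a run, and non-ACGT characters (N,
gaps) never lie inside a run.

Repeat units related by cyclic rotation or reverse complement describe the
same double-stranded repeat, so units are canonicalized into 16 *species*
groups: 2 for MNRs (A/T, C/G), 4 for DNRs (TA, CT/GA, CA/GT, GC) and 10 for
TNRs (AAC, AAG, AAT, ACC, GAC, ACT, CAG, AGG, ATC, CGG).  Degenerate words
whose smallest period is shorter than their length (AA, CCC, ...) belong to
a lower clade and are not DNR/TNR units.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import statistics
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PolytractRecord",
    "HingeRecord",
    "MOTIF_TO_SPECIES",
    "SPECIES_LABELS",
    "CLADE_BY_PERIOD",
    "MIN_LENGTH",
    "revcomp",
    "smallest_period",
    "canonical_species",
    "scan_sequence",
    "scan_genome",
    "find_hinges",
    "extend_adjacency",
    "merge_intervals",
    "summarize_catalog",
    "filter_long_tnr",
]

CLADE_BY_PERIOD = {1: "MNR", 2: "DNR", 3: "TNR"}
PERIOD_BY_CLADE = {v: k for k, v in CLADE_BY_PERIOD.items()}
#: minimum run length in nucleotides per unit length (6 units / 3 units / 3 units)
MIN_LENGTH = {1: 6, 2: 6, 3: 9}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ACGT = frozenset("ACGT")


def revcomp(s: str) -> str:
    """Reverse complement of an ACGT string."""
    return s.translate(_COMPLEMENT)[::-1]


def _orbit(unit: str) -> set[str]:
    """All cyclic rotations of ``unit`` and of its reverse complement."""
    rc = revcomp(unit)
    return {w[i:] + w[:i] for w in (unit, rc) for i in range(len(w))}


# Species groups keyed by their canonical label; the value is one
# representative unit whose rotation/reverse-complement orbit spans the group.
_GROUP_REPRESENTATIVES: dict[str, str] = {
    # MNR
    "A/T": "A",
    "C/G": "C",
    # DNR
    "TA": "TA",
    "CT/GA": "CT",
    "CA/GT": "CA",
    "GC": "GC",
    # TNR
    "AAC": "AAC",
    "AAG": "AAG",
    "AAT": "AAT",
    "ACC": "ACC",
    "GAC": "GAC",
    "ACT": "ACT",
    "CAG": "CAG",
    "AGG": "AGG",
    "ATC": "ATC",
    "CGG": "CGG",
}


def _build_catalog() -> dict[str, tuple[str, str]]:
    table: dict[str, tuple[str, str]] = {}
    for label, rep in _GROUP_REPRESENTATIVES.items():
        clade = CLADE_BY_PERIOD[len(rep)]
        for word in sorted(_orbit(rep)):
            prev = table.setdefault(word, (clade, label))
            if prev != (clade, label):  # pragma: no cover - catalog sanity
                raise AssertionError(f"word {word} assigned twice: {prev}")
    return table


#: every non-degenerate ACGT word of length 1-3 mapped to (clade, species)
MOTIF_TO_SPECIES: dict[str, tuple[str, str]] = _build_catalog()

#: species labels per clade, in catalog order
SPECIES_LABELS: dict[str, tuple[str, ...]] = {
    "MNR": ("A/T", "C/G"),
    "DNR": ("TA", "CT/GA", "CA/GT", "GC"),
    "TNR": ("AAC", "AAG", "AAT", "ACC", "GAC", "ACT", "CAG", "AGG", "ATC", "CGG"),
}


@dataclass(frozen=True, order=True)
class PolytractRecord:
    """One maximal perfect repeat run.

    ``start``/``end`` are 0-based half-open; ``unit_len`` is the smallest
    period of the enclosed sequence (1, 2 or 3).
    """

    chrom: str
    start: int
    end: int
    clade: str
    species: str
    unit_len: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def complete_units(self) -> int:
        return self.length // self.unit_len


@dataclass(frozen=True, order=True)
class HingeRecord:
    """A single-nucleotide breakpoint between two tandem polytracts.

    ``pos`` is the 0-based position of the separating base; it lies inside no
    polytract of any clade.  ``duplex`` is the unordered species pair of the
    two flanking tracts (stored sorted).
    """

    chrom: str
    pos: int
    left_species: str
    right_species: str

    @property
    def duplex(self) -> tuple[str, str]:
        return tuple(sorted((self.left_species, self.right_species)))


def smallest_period(s: str) -> int:
    """Least ``p >= 1`` with ``s[i] == s[i - p]`` for all ``i >= p``.

    Raises ``ValueError`` on an empty or non-ACGT string.
    """
    if not s:
        raise ValueError("empty string has no period")
    s = s.upper()
    if not _ACGT.issuperset(s):
        bad = sorted(set(s) - _ACGT)
        raise ValueError(f"non-ACGT character(s) {bad} in {s!r}")
    for p in range(1, len(s)):
        if all(s[i] == s[i - p] for i in range(p, len(s))):
            return p
    return len(s)


def canonical_species(unit: str) -> tuple[str, str]:
    """Map a repeat unit of length 1-3 to its (clade, species) group.

    The label is invariant under cyclic rotation and reverse complement.
    Degenerate homopolymer words (``AA``, ``CCC``...) are rejected: a run of
    such a unit is a run of a lower clade.  Note that a word like ``CTC``
    is a valid trimer unit even though the word itself has period 2 — the
    repeat ``CTCCTC...`` still has smallest period 3.
    """
    unit = unit.upper()
    if not 1 <= len(unit) <= 3:
        raise ValueError(f"unit length must be 1-3, got {unit!r}")
    if not _ACGT.issuperset(unit):
        raise ValueError(f"non-ACGT unit {unit!r}")
    if len(set(unit)) == 1 and len(unit) > 1:
        raise ValueError(f"degenerate homopolymer unit {unit!r}")
    return MOTIF_TO_SPECIES[unit]


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _true_runs(mask: np.ndarray) -> np.ndarray:
    """(k, 2) array of [start, stop) runs of True in a boolean array."""
    if mask.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    edged = np.diff(np.concatenate(([False], mask, [False])).astype(np.int8))
    starts = np.flatnonzero(edged == 1)
    stops = np.flatnonzero(edged == -1)
    return np.column_stack((starts, stops))


def scan_sequence(
    seq: str,
    chrom: str = "seq",
    clades: Iterable[str] = ("MNR", "DNR", "TNR"),
) -> list[PolytractRecord]:
    """All maximal perfect repeat runs in one sequence.

    Scanning is case-insensitive; non-ACGT characters terminate runs.  The
    per-clade scans are independent, so records of different clades may
    overlap; records of the same clade never do.  Output is sorted by
    ``(chrom, start)``.
    """
    clades = set(clades)
    unknown = clades - set(PERIOD_BY_CLADE)
    if unknown:
        raise ValueError(f"unknown clade(s) {sorted(unknown)}")
    if not seq:
        return []
    b = _encode(seq)
    valid = np.isin(b, _BASES)
    records: list[PolytractRecord] = []
    useq = seq.upper()
    for clade in ("MNR", "DNR", "TNR"):
        if clade not in clades:
            continue
        p = PERIOD_BY_CLADE[clade]
        if len(b) <= p:
            continue
        eq = valid[:-p] & valid[p:] & (b[:-p] == b[p:])
        for i, j in _true_runs(eq):
            start, end = int(i), int(j) + p
            if end - start < MIN_LENGTH[p]:
                continue
            unit = useq[start : start + p]
            # a run whose unit is itself periodic belongs to a lower clade
            if p == 2 and unit[0] == unit[1]:
                continue
            if p == 3 and unit[0] == unit[1] == unit[2]:
                continue
            _, species = MOTIF_TO_SPECIES[unit]
            records.append(PolytractRecord(chrom, start, end, clade, species, p))
    records.sort(key=lambda r: (r.chrom, r.start, r.unit_len))
    return records


def scan_genome(
    sequences: Mapping[str, str],
    clades: Iterable[str] = ("MNR", "DNR", "TNR"),
) -> list[PolytractRecord]:
    """Scan every sequence of a genome; records sorted by (chrom, start)."""
    records: list[PolytractRecord] = []
    for chrom in sequences:
        records.extend(scan_sequence(str(sequences[chrom]), chrom=chrom, clades=clades))
    records.sort(key=lambda r: (r.chrom, r.start, r.unit_len))
    return records


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping [start, end) intervals into a disjoint sorted set."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _occupied_by_chrom(tracts: Iterable[PolytractRecord]) -> dict[str, list[tuple[int, int]]]:
    per_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for t in tracts:
        per_chrom[t.chrom].append((t.start, t.end))
    return {c: merge_intervals(iv) for c, iv in per_chrom.items()}


# flanking-tract tie-break on equal length: monomer runs outrank dimer runs
# outrank trimer runs
_CLADE_PRIORITY = {"MNR": 2, "DNR": 1, "TNR": 0}


def find_hinges(
    tracts: Sequence[PolytractRecord],
    seq_lengths: Mapping[str, int] | None = None,
) -> list[HingeRecord]:
    """Single-nucleotide breakpoints between two tandem polytracts.

    A hinge position ``pos`` has some polytract ending exactly at ``pos``,
    another starting exactly at ``pos + 1``, and lies inside no polytract of
    any clade.  When several tracts share a boundary the longest abutting
    tract labels that side (clade priority MNR > DNR > TNR on ties).
    """
    ends: dict[tuple[str, int], list[PolytractRecord]] = defaultdict(list)
    starts: dict[tuple[str, int], list[PolytractRecord]] = defaultdict(list)
    for t in tracts:
        ends[(t.chrom, t.end)].append(t)
        starts[(t.chrom, t.start)].append(t)
    occupied = _occupied_by_chrom(tracts)
    occ_arrays = {
        c: (np.array([s for s, _ in iv]), np.array([e for _, e in iv]))
        for c, iv in occupied.items()
    }

    def inside(chrom: str, pos: int) -> bool:
        s, e = occ_arrays[chrom]
        i = np.searchsorted(s, pos, side="right") - 1
        return i >= 0 and pos < e[i]

    def pick(candidates: list[PolytractRecord]) -> PolytractRecord:
        return max(candidates, key=lambda t: (t.length, _CLADE_PRIORITY[t.clade]))

    hinges: list[HingeRecord] = []
    for (chrom, pos), left_candidates in ends.items():
        right_candidates = starts.get((chrom, pos + 1))
        if not right_candidates:
            continue
        if seq_lengths is not None and pos >= seq_lengths[chrom]:  # pragma: no cover
            continue
        if inside(chrom, pos):
            continue
        left = pick(left_candidates)
        right = pick(right_candidates)
        hinges.append(HingeRecord(chrom, pos, left.species, right.species))
    hinges.sort()
    return hinges


def extend_adjacency(
    tracts: Iterable[PolytractRecord],
    seq_lengths: Mapping[str, int],
) -> dict[str, list[tuple[int, int]]]:
    """Widen each tract by one nucleotide on both sides and merge.

    Extension is clipped at sequence boundaries.  Returns disjoint sorted
    intervals per chromosome.
    """
    per_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for t in tracts:
        L = seq_lengths[t.chrom]
        per_chrom[t.chrom].append((max(0, t.start - 1), min(L, t.end + 1)))
    return {c: merge_intervals(iv) for c, iv in sorted(per_chrom.items())}


def summarize_catalog(
    tracts: Sequence[PolytractRecord],
    seq_lengths: Mapping[str, int],
    by: str = "species",
) -> pd.DataFrame:
    """Per-bin census: count, nucleotides, % of genome, mean/median length,
    density per Mb.

    ``by`` is one of ``species``, ``clade`` or ``chromosome``.  Density is
    tracts per 10^6 nt of the bin's denominator: the chromosome length for
    chromosome bins, the whole genome for species/clade bins.  Genome size
    counts every base of the analyzed sequences, including Ns.  Empty bins
    are reported as zero rows with ``empty == True``.
    """
    N = int(sum(seq_lengths.values()))
    if by == "species":
        bins = [(c, s) for c in SPECIES_LABELS for s in SPECIES_LABELS[c]]
        keyer = lambda t: (t.clade, t.species)  # noqa: E731
        denom = {b: N for b in bins}
        index = pd.MultiIndex.from_tuples(bins, names=["clade", "species"])
    elif by == "clade":
        bins = list(SPECIES_LABELS)
        keyer = lambda t: t.clade  # noqa: E731
        denom = {b: N for b in bins}
        index = pd.Index(bins, name="clade")
    elif by == "chromosome":
        bins = sorted(seq_lengths)
        keyer = lambda t: t.chrom  # noqa: E731
        denom = {b: int(seq_lengths[b]) for b in bins}
        index = pd.Index(bins, name="chromosome")
    else:
        raise ValueError(f"unknown bin kind {by!r}")

    lengths: dict = {b: [] for b in bins}
    for t in tracts:
        key = keyer(t)
        if key in lengths:
            lengths[key].append(t.length)
    rows = []
    for b in bins:
        ls = lengths[b]
        nt = int(sum(ls))
        rows.append(
            {
                "count": len(ls),
                "nucleotides": nt,
                "percent_of_genome": 100.0 * nt / N,
                "mean_length": float(statistics.fmean(ls)) if ls else 0.0,
                "median_length": float(statistics.median(ls)) if ls else 0.0,
                "density_per_mb": 1e6 * len(ls) / denom[b],
                "empty": not ls,
            }
        )
    return pd.DataFrame(rows, index=index)


def filter_long_tnr(
    tracts: Iterable[PolytractRecord], min_len: int = 18
) -> list[PolytractRecord]:
    """TNR records spanning at least ``min_len`` nt (default 18 nt, i.e. six
    complete or incomplete trimer units)."""
    return [t for t in tracts if t.clade == "TNR" and t.length >= min_len]
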