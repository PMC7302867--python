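"""Synthetic genomes with planted repeats and feature sets with controlled enrichment.

The generator builds (i) repeat-free random backgrounds, (ii) genomes with
planted polytracts whose exact coordinates, species and hinge structure are
known (a truth set the scanner must recover), and (iii) point/interval
feature sets placed inside a territory with a designed probability
``pi = c * n/N`` so that the enrichment statistics have a known truth
(relative risk c, calibrated null at c = 1).

All randomness flows through one seeded :class:`numpy.random.Generator`;
identical seeds give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .enrichment import Interval, Territory
from .scanner import (
    MIN_LENGTH,
    MOTIF_TO_SPECIES,
    PolytractRecord,
    scan_sequence,
)

__all__ = [
    "PlantedTract",
    "SyntheticSpec",
    "generate_background",
    "plant_tracts",
    "generate_features",
    "random_planted_spec",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class PlantedTract:
    """One repeat to plant: ``n_units`` copies of ``unit`` plus
    ``partial_nt`` leading bases of one more unit, starting at ``pos``."""

    pos: int
    unit: str
    n_units: int
    partial_nt: int = 0

    @property
    def length(self) -> int:
        return len(self.unit) * self.n_units + self.partial_nt

    @property
    def end(self) -> int:
        return self.pos + self.length

    def sequence(self) -> str:
        return self.unit * self.n_units + self.unit[: self.partial_nt]

    def validate(self) -> None:
        unit = self.unit.upper()
        p = len(unit)
        if unit not in MOTIF_TO_SPECIES:
            raise ValueError(f"degenerate or invalid unit {unit!r}")
        if not 0 <= self.partial_nt < p:
            raise ValueError(f"partial_nt must be in [0, {p}), got {self.partial_nt}")
        if self.length < MIN_LENGTH[p]:
            raise ValueError(
                f"planted tract of {self.length} nt below the "
                f"{MIN_LENGTH[p]} nt minimum for unit length {p}"
            )

    def to_record(self, chrom: str) -> PolytractRecord:
        p = len(self.unit)
        clade, species = MOTIF_TO_SPECIES[self.unit.upper()]
        return PolytractRecord(chrom, self.pos, self.end, clade, species, p)


@dataclass
class SyntheticSpec:
    """Planted-repeat and feature-sampling parameters for one synthetic genome."""

    genome_length: int
    seed: int
    planted: list[PlantedTract] = field(default_factory=list)
    feature_m: int = 0
    enrichment_c: float = 1.0
    feature_length: int = 1


def generate_background(length: int, seed: int) -> str:
    """Random ACGT sequence containing no polytract of any clade.

    Starts from an i.i.d. uniform draw, then repeatedly breaks every
    qualifying run by substituting its center base with one differing from
    both neighbors, until a full scan comes back empty.  Deterministic for a
    given seed.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length, dtype=np.uint8)
    seq = list(np.frombuffer(_BASES.encode(), dtype=np.uint8)[codes].tobytes().decode())
    for _ in range(100):
        found = scan_sequence("".join(seq))
        if not found:
            return "".join(seq)
        for t in found:
            _break_run(seq, (t.start + t.end) // 2, rng)
    raise RuntimeError("background repair did not converge")  # pragma: no cover


def _break_run(
    seq: list[str], pos: int, rng: np.random.Generator, window: int = 40
) -> None:
    """Substitute seq[pos] so that no qualifying run passes through pos.

    Candidate bases (all three differing from the current one) are tried in
    random order; the first whose local rescan leaves no run covering pos is
    kept.  Splitting a long run can leave qualifying halves elsewhere; the
    callers' scan-and-repair loops catch those.
    """
    lo, hi = max(0, pos - window), min(len(seq), pos + window)
    cands = [b for b in _BASES if b != seq[pos]]
    rng.shuffle(cands)
    for b in cands:
        seq[pos] = b
        local = scan_sequence("".join(seq[lo:hi]))
        if not any(r.start <= pos - lo < r.end for r in local):
            return
    # no candidate is locally clean; keep the last (the original run is
    # still broken at pos) and let the caller retry elsewhere


def plant_tracts(
    background: str,
    planted: Sequence[PlantedTract],
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[str, list[PolytractRecord]]:
    """Write planted repeats into a repeat-free background.

    Plants must be separated by at least two background nucleotides, or by
    exactly one to request a hinge.  Background bases flanking each plant
    are locally repaired (never the planted bases themselves) until a full
    scan returns exactly the truth records.  Returns the genome and the
    truth records sorted by position.
    """
    order = sorted(planted, key=lambda t: t.pos)
    prev_end = None
    for t in order:
        t.validate()
        if t.pos < 0 or t.end > len(background):
            raise ValueError(f"plant at {t.pos} does not fit in the background")
        if prev_end is not None and t.pos - prev_end < 1:
            raise ValueError("overlapping or directly adjacent plant requests")
        prev_end = t.end
    seq = list(background.upper())
    protected = np.zeros(len(seq), dtype=bool)
    for t in order:
        seq[t.pos : t.end] = t.sequence().upper()
        protected[t.pos : t.end] = True
    truth = sorted(t.to_record(chrom) for t in order)
    truth_set = set(truth)

    rng = np.random.default_rng(seed)
    for _ in range(200):
        found = scan_sequence("".join(seq), chrom=chrom)
        spurious = [r for r in found if r not in truth_set]
        if not spurious and len(found) == len(truth):
            return "".join(seq), truth
        if not spurious:  # pragma: no cover - cannot lose a protected plant
            raise RuntimeError("planted tract lost during flank repair")
        for r in spurious:
            pos = _mutable_position(r, protected)
            _break_run(seq, pos, rng)
    raise RuntimeError("flank repair did not converge")  # pragma: no cover


def _mutable_position(record: PolytractRecord, protected: np.ndarray) -> int:
    """Background position inside a spurious run, closest to its center."""
    center = (record.start + record.end) // 2
    candidates = [i for i in range(record.start, record.end) if not protected[i]]
    if not candidates:  # pragma: no cover - spurious runs always touch background
        raise RuntimeError("spurious run entirely inside planted tracts")
    return min(candidates, key=lambda i: abs(i - center))


def generate_features(
    territory: Territory,
    M: int,
    c: float,
    seed: int,
    length: int = 1,
) -> list[Interval]:
    """Feature instances with designed in-territory probability pi = c * n/N.

    Each of the M instances independently lands fully inside the territory
    with probability pi (uniform over in-territory placements), else fully
    outside.  With c = 1 the placement is equivalent to a uniform draw over
    the genome and realizes the null of the binomial test; c > 1 gives an
    expected singleton relative risk of c.
    """
    if M <= 0:
        raise ValueError("M must be positive")
    if length < 1:
        raise ValueError("feature length must be >= 1")
    pi = c * territory.n / territory.N
    if not 0 <= pi <= 1:
        raise ValueError(f"c * n/N = {pi:.4g} outside [0, 1]")
    rng = np.random.default_rng(seed)

    inside_slots: list[tuple[str, int, int]] = []  # (chrom, start, n_starts)
    outside_slots: list[tuple[str, int, int]] = []
    for chrom, L in sorted(territory.seq_lengths.items()):
        iv = territory.intervals.get(chrom, [])
        for s, e in iv:
            if e - s >= length:
                inside_slots.append((chrom, s, e - s - length + 1))
        prev = 0
        for s, e in iv + [(L, L)]:
            if s - prev >= length:
                outside_slots.append((chrom, prev, s - prev - length + 1))
            prev = e
    if not inside_slots:
        raise ValueError("territory has no interval long enough for the feature length")
    if not outside_slots:
        raise ValueError("no outside room for the feature length")

    def draw(slots: list[tuple[str, int, int]], count: int) -> list[Interval]:
        weights = np.array([w for _, _, w in slots], dtype=float)
        picks = rng.choice(len(slots), size=count, p=weights / weights.sum())
        offsets = rng.integers(0, weights[picks].astype(np.int64))
        return [
            (slots[i][0], slots[i][1] + int(o), slots[i][1] + int(o) + length)
            for i, o in zip(picks, offsets)
        ]

    inside_mask = rng.random(M) < pi
    n_in = int(inside_mask.sum())
    feats = draw(inside_slots, n_in) + draw(outside_slots, M - n_in)
    perm = rng.permutation(M)
    return [feats[i] for i in perm]


def random_planted_spec(
    genome_length: int,
    n_tracts: int,
    n_hinge_pairs: int,
    rng: np.random.Generator,
    min_gap: int = 20,
) -> list[PlantedTract]:
    """Random plant layout: ``n_tracts`` isolated tracts plus
    ``n_hinge_pairs`` pairs separated by exactly one nucleotide."""
    units = sorted(MOTIF_TO_SPECIES)

    def random_tract(pos: int) -> PlantedTract:
        unit = units[int(rng.integers(len(units)))]
        p = len(unit)
        min_units = -(-MIN_LENGTH[p] // p)
        n_units = int(rng.integers(min_units, min_units + 6))
        partial = int(rng.integers(0, p))
        if n_units * p + partial < MIN_LENGTH[p]:
            partial = 0
            n_units = max(n_units, min_units)
        return PlantedTract(pos, unit, n_units, partial)

    # widest possible footprint: pair of two tracts + 1-nt separator
    max_foot = 2 * (3 * 9 + 2) + 1
    slot = max_foot + min_gap
    n_slots = genome_length // slot
    if n_slots < n_tracts + n_hinge_pairs:
        raise ValueError("genome too small for the requested plant count")
    chosen = rng.choice(n_slots, size=n_tracts + n_hinge_pairs, replace=False)
    plants: list[PlantedTract] = []
    for rank, islot in enumerate(sorted(chosen.tolist())):
        pos = islot * slot + min_gap // 2
        first = random_tract(pos)
        plants.append(first)
        if rank < n_hinge_pairs:
            plants.append(random_tract(first.end + 1))
    return sorted(plants, key=lambda t: t.pos)
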