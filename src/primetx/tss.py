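"""Library normalization and primary-position (TSS) calling.

The two-step normalization scheme: (1) every treated library is scaled to a
common size of 1e8 reads and positions with >=500 scaled read starts and a
read-start/coverage ratio above 0.5 are declared true primary positions;
(2) a library-specific correction factor — the across-library mean primary
fraction divided by this library's primary fraction — is applied to the
read-start counts, compensating for variable 5'-PPP enrichment efficiency.
The untreated library is scaled to counts per 1e8 but takes no correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CONDITIONS, Library, Thresholds, Track, TSSRecord

__all__ = [
    "NormalizedLibrary",
    "scale_library",
    "call_true_primary_positions",
    "compute_correction_factors",
    "normalize_libraries",
    "build_tss_set",
]


@dataclass
class NormalizedLibrary:
    """A treated library after scaling, primary-position calling and correction."""

    library_id: str
    condition: str
    library: Library  # scaled tracks; read_starts additionally corrected
    correction_factor: float
    primary_positions: dict  # strand -> sorted int array

    def __post_init__(self):
        if not self.correction_factor > 0:
            raise ValueError("correction factor must be positive")


def scale_library(lib: Library, scale_target: float = 1e8) -> Library:
    """Scale every track by scale_target / raw_total."""
    if lib.raw_total <= 0:
        raise ValueError(f"library {lib.library_id}: raw_total must be positive")
    factor = scale_target / lib.raw_total
    tracks = {key: t.scaled(factor) for key, t in lib.tracks.items()}
    return Library(lib.library_id, lib.condition, lib.treated, tracks, lib.raw_total)


def call_true_primary_positions(read_starts: Track, coverage: Track,
                                th: Thresholds) -> np.ndarray:
    """Positions passing both primary-position criteria, as a sorted array.

    A position qualifies iff its scaled read-start count is >= the minimum
    (500 by default) and the start/coverage ratio exceeds 0.5. A position
    with zero coverage but nonzero starts counts as ratio 1 (in real data
    coverage >= starts by construction; this guards degenerate input).
    """
    if len(read_starts) != len(coverage):
        raise ValueError("read_starts and coverage tracks differ in length")
    if read_starts.strand != coverage.strand or read_starts.seq_id != coverage.seq_id:
        raise ValueError("read_starts and coverage tracks are not from the same strand/replicon")
    s = read_starts.values
    c = coverage.values
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(c > 0, s / np.where(c > 0, c, 1.0), np.where(s > 0, 1.0, 0.0))
    mask = (s >= th.min_read_starts) & (ratio > th.min_start_coverage_ratio)
    return np.flatnonzero(mask)


def _primary_fraction(lib: Library, primary: dict) -> float:
    """Fraction of a library's read-start counts falling on its primary positions."""
    total = 0.0
    on_primary = 0.0
    for strand in "+-":
        v = lib.track("read_starts", strand).values
        total += float(v.sum())
        pos = primary.get(strand)
        if pos is not None and len(pos):
            on_primary += float(v[pos].sum())
    if total == 0:
        return 0.0
    return on_primary / total


def compute_correction_factors(scaled_libs: list[Library],
                               primaries: list[dict]) -> list[float]:
    """Library-specific correction factors from primary-count fractions.

    Each library's factor is the across-library mean primary fraction
    divided by its own primary fraction, so libraries with weaker 5'
    enrichment are scaled up. A library with zero primary counts has no
    defined factor and is an error.
    """
    fractions = []
    for lib, primary in zip(scaled_libs, primaries):
        frac = _primary_fraction(lib, primary)
        if frac <= 0:
            raise ValueError(
                f"library {lib.library_id}: no counts at primary positions; "
                "correction factor undefined"
            )
        fractions.append(frac)
    target = float(np.mean(fractions))
    return [target / f for f in fractions]


def normalize_libraries(treated: list[Library], th: Thresholds | None = None) -> list[NormalizedLibrary]:
    """Full two-step normalization of a strain's treated libraries.

    Positions are called on the scaled-but-uncorrected tracks; the
    correction factor is then applied to the read-start tracks only (it is
    a count correction, not a coverage model).
    """
    th = th or Thresholds()
    scaled = [scale_library(lib, th.scale_target) for lib in treated]
    primaries = []
    for lib in scaled:
        primaries.append(
            {
                strand: call_true_primary_positions(
                    lib.track("read_starts", strand), lib.track("coverage", strand), th
                )
                for strand in "+-"
            }
        )
    factors = compute_correction_factors(scaled, primaries)
    out = []
    for lib, primary, factor in zip(scaled, primaries, factors):
        tracks = dict(lib.tracks)
        for strand in "+-":
            tracks[("read_starts", strand)] = tracks[("read_starts", strand)].scaled(factor)
        corrected = Library(lib.library_id, lib.condition, lib.treated, tracks, lib.raw_total)
        out.append(
            NormalizedLibrary(
                library_id=lib.library_id,
                condition=lib.condition,
                library=corrected,
                correction_factor=factor,
                primary_positions=primary,
            )
        )
    return out


def build_tss_set(libs: list[NormalizedLibrary], strain_id: str,
                  seq_id: str, merge_window: int = 0) -> list[TSSRecord]:
    """Union per-condition primary positions into one TSS table.

    One record per (seq_id, strand, position) that is a true primary
    position in at least one condition. The counts vector reports the
    corrected scaled read-start value in every condition — a condition
    where the position did not pass the calling criteria still contributes
    its corrected value, not zero.

    TSSs are single-nucleotide positions and are not clustered by default;
    with ``merge_window`` > 0, runs of positions within the window collapse
    to the member with the largest summed corrected count (ties to the
    lower coordinate).
    """
    if not libs:
        return []
    by_condition = {lib.condition: lib for lib in libs}

    def total_count(strand: str, pos: int) -> float:
        return sum(lib.library.track("read_starts", strand).values[pos]
                   for lib in libs)

    records: list[TSSRecord] = []
    for strand in "+-":
        union: set[int] = set()
        for lib in libs:
            union.update(int(p) for p in lib.primary_positions.get(strand, ()))
        positions = sorted(union)
        if merge_window > 0 and positions:
            merged = []
            cluster = [positions[0]]
            for pos in positions[1:]:
                if pos - cluster[-1] <= merge_window:
                    cluster.append(pos)
                else:
                    merged.append(max(cluster, key=lambda p: (total_count(strand, p), -p)))
                    cluster = [pos]
            merged.append(max(cluster, key=lambda p: (total_count(strand, p), -p)))
            positions = merged
        for pos in positions:
            counts = np.zeros(len(CONDITIONS))
            for j, cond in enumerate(CONDITIONS):
                lib = by_condition.get(cond)
                if lib is not None:
                    counts[j] = lib.library.track("read_starts", strand).values[pos]
            records.append(
                TSSRecord(strain_id=strain_id, seq_id=seq_id, strand=strand,
                          position=pos, counts=counts)
            )
    return records
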