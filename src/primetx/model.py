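"""Domain types and coordinate conventions.

All internal coordinates are 0-based half-open on the forward strand of a
single replicon. External formats (GFF3, result tables) use 1-based
inclusive coordinates; the conversion helpers below are the only place the
two conventions meet.

A "position" of a TSS is the genomic index of the first transcribed
nucleotide (0-based internally). For a minus-strand feature the transcript
runs right-to-left, so its TSS is the *end*-most genomic coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "CONDITIONS",
    "GenomeSequence",
    "GeneAnnotation",
    "Track",
    "Library",
    "Thresholds",
    "TSSRecord",
    "TranscriptionalUnit",
    "SegmentationParams",
    "ActuatonParams",
    "to_internal",
    "to_external",
    "revcomp",
    "translate",
]

#: Fixed condition order used for every expression vector and output column.
CONDITIONS = ("15C", "42C", "-C", "dark", "-Fe", "HL", "-N", "-P", "stat", "exp")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_CODON_TABLE = {}


def _build_codon_table() -> dict:
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for codon in standard_dna_table.stop_codons:
        table[codon] = "*"
    return table


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase nucleotide string (N self-pairs)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a nucleotide CDS (length multiple of 3); stops become '*',
    codons containing N become 'X'."""
    global _CODON_TABLE
    if not _CODON_TABLE:
        _CODON_TABLE = _build_codon_table()
    if len(seq) % 3:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    out = []
    for i in range(0, len(seq), 3):
        out.append(_CODON_TABLE.get(seq[i : i + 3], "X"))
    return "".join(out)


def to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    if start_1based < 1 or end_1based < start_1based:
        raise ValueError(f"invalid 1-based interval {start_1based}..{end_1based}")
    return start_1based - 1, end_1based


def to_external(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    if start < 0 or end <= start:
        raise ValueError(f"invalid 0-based half-open interval [{start}, {end})")
    return start + 1, end


@dataclass(frozen=True)
class GenomeSequence:
    strain_id: str
    seq_id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError("empty genome sequence")
        if not set(self.residues) <= set("ACGTN"):
            raise ValueError("genome residues must be uppercase ACGTN")

    def __len__(self) -> int:
        return len(self.residues)

    def fetch(self, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end) on the requested strand (5'->3')."""
        sub = self.residues[start:end]
        return sub if strand == "+" else revcomp(sub)


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated gene; ``start``/``end`` are internal 0-based half-open."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    kind: str = "protein_coding"  # protein_coding | known_sRNA | other
    product: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval for gene {self.gene_id}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Genomic index of the first transcribed/translated base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class Track:
    """Dense per-position signal on one strand of one replicon."""

    strain_id: str
    seq_id: str
    strand: str
    values: np.ndarray
    semantics: str = "read_starts"  # read_starts | coverage

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.strand not in ("+", "-"):
            raise ValueError("track strand must be '+' or '-'")
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValueError("track values must be a non-empty 1-D vector")
        if np.any(self.values < 0):
            raise ValueError("track values must be non-negative")
        if self.semantics not in ("read_starts", "coverage"):
            raise ValueError(f"unknown track semantics {self.semantics!r}")

    def __len__(self) -> int:
        return len(self.values)

    def scaled(self, factor: float) -> "Track":
        return Track(self.strain_id, self.seq_id, self.strand,
                     self.values * factor, self.semantics)


@dataclass
class Library:
    """One sequencing library: read-start and coverage tracks on both strands."""

    library_id: str
    condition: str  # one of CONDITIONS, or "untreated"
    treated: bool
    tracks: dict  # (semantics, strand) -> Track
    raw_total: float

    def __post_init__(self):
        required = {(sem, st) for sem in ("read_starts", "coverage") for st in "+-"}
        if set(self.tracks) != required:
            missing = sorted(required - set(self.tracks))
            raise ValueError(f"library {self.library_id}: missing tracks {missing}")
        if self.raw_total < 0:
            raise ValueError("raw_total must be non-negative")

    def track(self, semantics: str, strand: str) -> Track:
        return self.tracks[(semantics, strand)]


@dataclass(frozen=True)
class Thresholds:
    """Every numeric decision threshold of the analysis, with its default.

    Defaults follow the published analysis protocol: treated libraries are
    scaled to 1e8 reads; a position is a true primary position when it
    carries >=500 scaled read starts and the read-start/coverage ratio
    exceeds 0.5; antisense relations require >=20 nt overlap; ortholog
    aTSS/iTSS positions may differ by at most 10 nt; free-standing
    transcripts are conserved at e-value <= 1e-5 with query coverage >= 0.5;
    differential expression requires |FC| >= 2 at posterior >= 0.95; a UEF
    above 5 marks condition-specific induction; leaderless mRNAs start at
    the A of AUG or within the 10 nt upstream; ortholog expression profiles
    are clustered with k-means at k = 10.
    """

    scale_target: float = 1e8
    min_read_starts: float = 500.0
    min_start_coverage_ratio: float = 0.5
    antisense_overlap_min: int = 20
    ortholog_tss_offset_max: int = 10
    ntss_evalue_max: float = 1e-5
    ntss_qcov_min: float = 0.5
    fc_min: float = 2.0
    posterior_min: float = 0.95
    uef_high: float = 5.0
    leaderless_window: int = 10
    kmeans_k: int = 10

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if not value > 0:
                raise ValueError(f"threshold {name} must be positive, got {value}")


@dataclass
class TSSRecord:
    """A called primary position.

    ``counts`` holds the corrected, scaled read-start value per condition in
    :data:`CONDITIONS` order. ``classes`` is filled in during TU
    classification.
    """

    strain_id: str
    seq_id: str
    strand: str
    position: int  # 0-based index of the +1 nucleotide
    counts: np.ndarray
    classes: tuple = ()

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(CONDITIONS),):
            raise ValueError("counts vector must have one entry per condition")
        if not np.any(self.counts > 0):
            raise ValueError("a TSS must have a positive count in >=1 condition")

    @property
    def max_condition(self) -> str:
        return CONDITIONS[int(np.argmax(self.counts))]

    @property
    def key(self) -> tuple:
        return (self.seq_id, self.strand, self.position)


@dataclass
class TranscriptionalUnit:
    """A strand-specific interval anchored at one TSS.

    ``labels`` is the ordered class subset drawn from (g, a, i, n); its
    joined form (e.g. ``gaTU``) is the field's composite notation.
    """

    tu_id: str
    strain_id: str
    seq_id: str
    strand: str
    start: int
    end: int
    tss: TSSRecord
    member_genes: list = field(default_factory=list)
    labels: tuple = ()
    utr5_len: Optional[int] = None
    utr3_len: Optional[int] = None
    flags: tuple = ()

    @property
    def label_str(self) -> str:
        return "".join(self.labels) + "TU"

    @property
    def expression(self) -> np.ndarray:
        return self.tss.counts

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass(frozen=True)
class SegmentationParams:
    """Coverage-based TU segmentation (running-maximum fractional rule).

    The default fraction (0.04) deliberately sits below the smallest
    read-through level an actuaton may retain, so that a unit with
    substoichiometric read-through into a downstream gene is kept intact
    rather than truncated at the sRNA 3' boundary.
    """

    min_coverage_fraction: float = 0.04
    max_gap: int = 50
    max_tu_length: int = 20_000

    def __post_init__(self):
        if not 0 < self.min_coverage_fraction < 1:
            raise ValueError("min_coverage_fraction must lie in (0, 1)")
        if self.max_gap < 1 or self.max_tu_length < 1:
            raise ValueError("max_gap and max_tu_length must be positive")


@dataclass(frozen=True)
class ActuatonParams:
    """Operational thresholds for actuaton calling.

    The element itself is qualitative — an abundant, discrete sRNA reading
    through into a downstream gene that has no gTSS of its own — so these
    bounds are explicit modelling choices, all overridable.
    """

    min_abundance_percentile: float = 75.0
    max_drop_ratio: float = 0.5
    min_readthrough: float = 0.02
    max_srna_len: int = 400
    gene_search_window: int = 500
    flank: int = 20  # averaging window on either side of a candidate drop

    def __post_init__(self):
        if not 0 < self.max_drop_ratio < 1:
            raise ValueError("max_drop_ratio must lie in (0, 1)")
        if not 0 <= self.min_readthrough < self.max_drop_ratio:
            raise ValueError("min_readthrough must lie in [0, max_drop_ratio)")
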