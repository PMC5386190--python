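"""Actuaton detection.

An actuaton is a genetic element in which an abundant sRNA accumulates as a
discrete transcript — visible as a sharp coverage drop at its 3' end — while
transcriptional read-through past that boundary supplies the mRNA of a
downstream sense gene that has no gTSS of its own. Detection therefore
requires, for a candidate TU: an sRNA-type 5' part (free-standing TSS, an
annotated known sRNA at the TSS, or a long 5' UTR preceding the first
gene), a coverage drop within the sRNA length bound, a downstream in-TU
sense gene close behind the drop, the absence of any other TU supplying
that gene with a gTSS, high TSS abundance, and a read-through fraction that
is substantial but substoichiometric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    ActuatonParams,
    GeneAnnotation,
    Track,
    TranscriptionalUnit,
    TSSRecord,
)

__all__ = ["ActuatonCall", "find_coverage_drop", "detect_actuatons"]


@dataclass
class ActuatonCall:
    tu_id: str
    srna_start: int  # genomic half-open interval of the sRNA part
    srna_end: int
    downstream_gene: str
    drop_ratio: float
    readthrough_fraction: float
    srna_abundance_rank: float  # percentile among all TSS maximal counts
    flags: tuple = ()


def _relative_coverage(tu: TranscriptionalUnit, coverage: Track) -> np.ndarray:
    """Coverage inside the TU in transcript orientation (index 0 = TSS)."""
    v = coverage.values[tu.start: tu.end]
    return v if tu.strand == "+" else v[::-1]


def find_coverage_drop(tu: TranscriptionalUnit, coverage: Track,
                       params: ActuatonParams | None = None) -> Optional[tuple[int, float]]:
    """The most 5' discrete coverage drop within the sRNA length bound.

    Scans transcript-relative offsets and returns (offset, ratio) for the
    first position where the mean coverage over the following ``flank`` nt
    divided by the mean over the preceding ``flank`` nt is at most
    ``max_drop_ratio``; None when no such drop exists. The offset marks the
    first position *after* the sRNA 3' end.
    """
    params = params or ActuatonParams()
    v = _relative_coverage(tu, coverage)
    if len(v) <= 2 * params.flank:
        return None
    limit = min(len(v) - params.flank, params.max_srna_len)
    f = params.flank
    for off in range(f, limit):
        before = v[off - f: off].mean()
        if before <= 0:
            continue
        after = v[off: off + f].mean()
        ratio = after / before
        if ratio <= params.max_drop_ratio:
            # refine to the steepest single-position step near the window
            # crossing, then re-evaluate the flank-mean ratio there
            lo = max(1, off - f)
            hi = min(len(v) - 1, off + f)
            steps = v[lo - 1: hi] - v[lo: hi + 1]
            p = lo + int(np.argmax(steps))
            before = v[max(0, p - f): p].mean()
            after = v[p: p + f].mean()
            if before > 0 and after / before <= params.max_drop_ratio:
                off, ratio = p, after / before
            return off, float(ratio)
    return None


def _to_genomic(tu: TranscriptionalUnit, offset: int) -> int:
    return tu.start + offset if tu.strand == "+" else tu.end - 1 - offset


def _genes_with_own_gtss(tus: list[TranscriptionalUnit]) -> dict:
    """gene_id -> set of TU ids whose unit starts at a gTSS for this gene
    as its first member gene (the gene's 'own' promoter)."""
    owners: dict[str, set] = {}
    for tu in tus:
        if "g" not in tu.labels or not tu.member_genes:
            continue
        first = tu.member_genes[0]
        owners.setdefault(first.gene_id, set()).add(tu.tu_id)
    return owners


def _eligible_five_prime(tu: TranscriptionalUnit, genes: list[GeneAnnotation],
                         drop_offset: int, tolerance: int = 5) -> tuple[bool, tuple]:
    """Is the TU's 5' part sRNA-like?

    True when the TSS is free-standing (nTSS), coincides with an annotated
    known sRNA's start, or — for a gene-covering TU — the drop precedes the
    first member gene (a 5'-UTR-derived sRNA; flagged ``utr_derived``).
    """
    if "nTSS" in tu.tss.classes:
        return True, ()
    for g in genes:
        if g.kind != "known_sRNA" or g.strand != tu.strand:
            continue
        if abs(g.five_prime - tu.tss.position) <= tolerance:
            return True, ()
    if "g" in tu.labels and tu.member_genes:
        first = tu.member_genes[0]
        drop_pos = _to_genomic(tu, drop_offset)
        before_first = (drop_pos <= first.start if tu.strand == "+"
                        else drop_pos >= first.end - 1)
        if before_first:
            return True, ("utr_derived",)
    return False, ()


def detect_actuatons(tus: list[TranscriptionalUnit], tss_records: list[TSSRecord],
                     genes: list[GeneAnnotation], coverage: dict,
                     params: ActuatonParams | None = None) -> list[ActuatonCall]:
    """Scan all TUs for actuaton arrangements.

    ``coverage`` maps strand -> untreated coverage Track. The abundance
    rank of a candidate is the percentile of its TSS's maximal corrected
    count among all called TSSs.
    """
    params = params or ActuatonParams()
    if not tus:
        return []
    max_counts = np.array([float(t.counts.max()) for t in tss_records])
    owners = _genes_with_own_gtss(tus)
    calls = []
    for tu in sorted(tus, key=lambda t: (t.seq_id, t.start, t.strand)):
        if len(tu) <= 50:
            continue
        cov = coverage[tu.strand]
        drop = find_coverage_drop(tu, cov, params)
        if drop is None:
            continue
        drop_offset, drop_ratio = drop
        eligible, flags = _eligible_five_prime(tu, genes, drop_offset)
        if not eligible:
            continue
        # abundance: percentile of this TSS's maximal count among all TSSs
        own_max = float(tu.tss.counts.max())
        rank = 100.0 * np.mean(max_counts <= own_max)
        if rank < params.min_abundance_percentile:
            continue
        gene = _first_gene_after_drop(tu, drop_offset, params)
        if gene is None:
            continue
        if owners.get(gene.gene_id, set()) - {tu.tu_id}:
            continue  # the downstream gene has a gTSS of its own
        v = _relative_coverage(tu, cov)
        srna_mean = v[:drop_offset].mean()
        gene_off0, gene_off1 = _gene_offsets(tu, gene)
        gene_body = v[gene_off0: min(gene_off1, len(v))]
        if srna_mean <= 0 or len(gene_body) == 0:
            continue
        readthrough = float(gene_body.mean() / srna_mean)
        if not (params.min_readthrough <= readthrough < params.max_drop_ratio):
            continue
        drop_pos = _to_genomic(tu, drop_offset)
        if tu.strand == "+":
            srna_start, srna_end = tu.start, drop_pos
        else:
            srna_start, srna_end = drop_pos + 1, tu.end
        calls.append(
            ActuatonCall(
                tu_id=tu.tu_id,
                srna_start=srna_start,
                srna_end=srna_end,
                downstream_gene=gene.gene_id,
                drop_ratio=drop_ratio,
                readthrough_fraction=readthrough,
                srna_abundance_rank=float(rank),
                flags=flags,
            )
        )
    return calls


def _first_gene_after_drop(tu: TranscriptionalUnit, drop_offset: int,
                           params: ActuatonParams) -> Optional[GeneAnnotation]:
    """First sense member gene starting downstream of the drop, within the
    search window and inside the TU."""
    candidates = []
    for g in tu.member_genes:
        if g.strand != tu.strand:
            continue
        off0, _ = _gene_offsets(tu, g)
        if drop_offset <= off0 <= drop_offset + params.gene_search_window:
            candidates.append((off0, g))
    if not candidates:
        return None
    return min(candidates)[1]


def _gene_offsets(tu: TranscriptionalUnit, gene: GeneAnnotation) -> tuple[int, int]:
    """Gene body as transcript-relative offsets within the TU."""
    if tu.strand == "+":
        return gene.start - tu.start, gene.end - tu.start
    return tu.end - gene.end, tu.end - gene.start
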