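"""Transcriptional-unit segmentation, classification, UTRs and leaderless mRNAs.

A TU is anchored at its TSS and extended downstream over the untreated
(secondary) coverage with a running-maximum fractional rule: the unit
continues while coverage stays above ``min_coverage_fraction`` of the
maximum seen since the TSS, and terminates after ``max_gap`` consecutive
sub-threshold positions.

Classification follows the g/a/i/n scheme: *g* when one or more annotated
genes are covered in sense, *a* when the unit is antisense to a gene or to
another TU with an overlap of at least 20 nt, *i* when the TSS lies
strictly inside a sense gene, and *n* when it is free-standing. A TU may
carry several labels (e.g. gaTU, gaiTU); they are emitted in canonical
g, a, i order.
"""

from __future__ import annotations

import numpy as np

from .model import (
    CONDITIONS,
    GeneAnnotation,
    SegmentationParams,
    Thresholds,
    Track,
    TranscriptionalUnit,
    TSSRecord,
)

__all__ = [
    "segment_tu",
    "build_tus",
    "classify_tus",
    "compute_utrs",
    "detect_leaderless",
]


def segment_tu(tss: TSSRecord, coverage: Track,
               params: SegmentationParams | None = None) -> tuple[int, int, tuple]:
    """Segment the TU interval downstream of a TSS.

    Returns (start, end, flags) as a 0-based half-open interval whose
    strand-aware 5' boundary is the TSS position. A TSS with zero coverage
    at its own position yields a 1-nt unit flagged ``zero_coverage``.
    """
    params = params or SegmentationParams()
    if coverage.strand != tss.strand:
        raise ValueError("coverage track strand does not match the TSS strand")
    v = coverage.values
    pos = tss.position
    if not 0 <= pos < len(v):
        raise ValueError("TSS position outside the genome")
    if v[pos] <= 0:
        return pos, pos + 1, ("zero_coverage",)
    step = 1 if tss.strand == "+" else -1
    run_max = v[pos]
    last_good = pos
    gap = 0
    p = pos + step
    while 0 <= p < len(v) and abs(p - pos) < params.max_tu_length:
        if v[p] >= params.min_coverage_fraction * run_max:
            run_max = max(run_max, v[p])
            last_good = p
            gap = 0
        else:
            gap += 1
            if gap > params.max_gap:
                break
        p += step
    if tss.strand == "+":
        return pos, last_good + 1, ()
    return last_good, pos + 1, ()


def build_tus(tss_records: list[TSSRecord], untreated_coverage: dict,
              strain_id: str, params: SegmentationParams | None = None) -> list[TranscriptionalUnit]:
    """Segment one TU per TSS; ``untreated_coverage`` maps strand -> Track.

    TU ids are assigned in genomic order (plus strand before minus at equal
    coordinates) so reruns are deterministic.
    """
    tus = []
    ordered = sorted(tss_records, key=lambda t: (t.seq_id, t.position, t.strand))
    for i, tss in enumerate(ordered, start=1):
        start, end, flags = segment_tu(tss, untreated_coverage[tss.strand], params)
        tus.append(
            TranscriptionalUnit(
                tu_id=f"{strain_id}_TU{i:04d}",
                strain_id=strain_id,
                seq_id=tss.seq_id,
                strand=tss.strand,
                start=start,
                end=end,
                tss=tss,
                flags=flags,
            )
        )
    return tus


def _host_gene(tss: TSSRecord, genes: list[GeneAnnotation]) -> GeneAnnotation | None:
    """The sense gene holding the TSS strictly inside its body, if any.

    'Strictly inside' excludes the first and last positions of the gene, so
    a TSS at the start codon's A anchors a leaderless gTU, not an iTU.
    """
    for g in genes:
        if g.kind == "known_sRNA":
            continue
        if g.strand == tss.strand and g.start < tss.position < g.end - 1:
            return g
    return None


def classify_tus(tus: list[TranscriptionalUnit], genes: list[GeneAnnotation],
                 th: Thresholds | None = None) -> None:
    """Assign class labels, member genes and TSS classes in place.

    All TUs of both strands must be present: the antisense relation is
    evaluated against annotated genes *and* against other TUs.
    """
    th = th or Thresholds()
    # known-sRNA annotations mark sRNA loci but do not define gene coverage:
    # a TU over such a locus stays free-standing unless it reaches a gene
    genes = [g for g in genes if g.kind != "known_sRNA"]
    for tu in tus:
        sense = [g for g in genes
                 if g.strand == tu.strand and tu.overlap(g.start, g.end) > 0]
        sense.sort(key=lambda g: g.start, reverse=(tu.strand == "-"))
        host = _host_gene(tu.tss, genes)
        labels = []
        g_members = [g for g in sense if host is None or g.gene_id != host.gene_id]
        if g_members:
            labels.append("g")
            # the host gene is still listed as a member when the unit runs
            # beyond it into a downstream gene
            members = sense
        else:
            members = g_members
        anti = any(
            g.strand != tu.strand and tu.overlap(g.start, g.end) >= th.antisense_overlap_min
            for g in genes
        ) or any(
            other.strand != tu.strand and other.seq_id == tu.seq_id
            and tu.overlap(other.start, other.end) >= th.antisense_overlap_min
            for other in tus
        )
        if anti:
            labels.append("a")
        if host is not None:
            labels.append("i")
        if not labels:
            labels = ["n"]
        tu.labels = tuple(labels)
        tu.member_genes = members
        tu.tss.classes = (_tss_class(tu, host),)


def _tss_class(tu: TranscriptionalUnit, host: GeneAnnotation | None) -> str:
    if host is not None:
        return "iTSS"
    if "g" in tu.labels:
        return "gTSS"
    if "a" in tu.labels:
        return "aTSS"
    return "nTSS"


def compute_utrs(tu: TranscriptionalUnit) -> None:
    """Fill in 5'/3' UTR lengths for gene-covering TUs (in place).

    utr5 is the distance from the TSS to the first member gene's start
    codon; utr3 from the last member gene's stop to the TU end. Both may be
    zero. Non-g TUs keep both undefined; a TSS inside the first gene leaves
    utr5 undefined with an ``utr5_undefined`` flag.
    """
    if "g" not in tu.labels or not tu.member_genes:
        return
    first = tu.member_genes[0]
    last = tu.member_genes[-1]
    if tu.strand == "+":
        utr5 = first.start - tu.tss.position
        utr3 = tu.end - last.end
    else:
        utr5 = tu.tss.position - (first.end - 1)
        utr3 = last.start - tu.start
    if utr5 < 0:
        tu.flags = tu.flags + ("utr5_undefined",)
    else:
        tu.utr5_len = int(utr5)
    tu.utr3_len = max(0, int(utr3))


def detect_leaderless(tss_records: list[TSSRecord], genes: list[GeneAnnotation],
                      th: Thresholds | None = None) -> list[GeneAnnotation]:
    """Genes whose mRNA is leaderless.

    A gene is flagged when a gTSS maps to the A of its AUG or to the 10 nt
    immediately upstream (a strand-aware closed window of 11 positions).
    """
    th = th or Thresholds()
    w = th.leaderless_window
    gtss_pos = {
        (t.strand, t.position) for t in tss_records if "gTSS" in t.classes
    }
    flagged = []
    for g in genes:
        if g.kind != "protein_coding":
            continue
        if g.strand == "+":
            window = range(g.start - w, g.start + 1)
        else:
            window = range(g.end - 1, g.end + w)
        if any((g.strand, p) in gtss_pos for p in window):
            flagged.append(g)
    return flagged
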