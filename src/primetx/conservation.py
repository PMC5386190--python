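"""Cross-strain TSS conservation and promoter-divergence scanning.

Conservation is decided per TSS class:

* gTSS — conserved when both orthologous genes are transcribed from a gTSS
  (any position) under at least one condition;
* aTSS / iTSS — positions are projected between strains through the global
  protein alignment of the orthologous gene the TSS lies within (sense for
  iTSS, antisense for aTSS) and must agree within 10 nt;
* nTSS — the free-standing transcript sequence is searched against the
  partner genome (e-value <= 1e-5, query coverage >= 50%); a qualifying hit
  overlapping a partner nTU is "conserved as nTU", otherwise the locus is
  conserved but classified differently.

Promoters of strain-specific TSSs are compared by aligning the upstream
windows of the homologous loci; the −10 element is taken as positions
−12..−7 relative to the TSS (+1 = TSS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alignment import (
    LocalAlignParams,
    ProteinAlignment,
    align_proteins,
    align_windows_global,
    local_align_search,
)
from .model import (
    GeneAnnotation,
    GenomeSequence,
    Thresholds,
    TranscriptionalUnit,
    TSSRecord,
    revcomp,
    translate,
)

__all__ = [
    "OrthologPair",
    "ConservationRecord",
    "PromoterReport",
    "build_ortholog_pairs",
    "conserved_gtss",
    "map_position_via_protein",
    "conserved_internal_antisense_tss",
    "conserved_ntss",
    "promoter_divergence",
]


@dataclass
class OrthologPair:
    gene_a: GeneAnnotation
    gene_b: GeneAnnotation
    alignment: ProteinAlignment

    @property
    def percent_identity(self) -> float:
        return self.alignment.percent_identity


@dataclass
class ConservationRecord:
    tss_class: str
    verdict: str  # conserved | conserved_classified_differently | strain_specific_a | strain_specific_b
    gene_a: Optional[str] = None
    gene_b: Optional[str] = None
    tss_a: Optional[TSSRecord] = None
    tss_b: Optional[TSSRecord] = None
    evidence: dict = field(default_factory=dict)


@dataclass
class PromoterReport:
    tss: TSSRecord
    verdict: str  # ok | unalignable
    window_a: str = ""
    window_b: str = ""
    mismatches: list = field(default_factory=list)  # (pos relative to TSS, base_a, base_b)
    minus10_a: str = ""
    minus10_b: str = ""
    minus10_mismatch: bool = False


def build_ortholog_pairs(id_pairs, genes_a, genes_b,
                         genome_a: GenomeSequence, genome_b: GenomeSequence) -> list[OrthologPair]:
    """Translate and globally align each ortholog gene pair.

    Gene IDs referenced by the table but absent from the annotation are an
    error listing the offenders.
    """
    by_id_a = {g.gene_id: g for g in genes_a}
    by_id_b = {g.gene_id: g for g in genes_b}
    missing = [gid for gid, _ in id_pairs if gid not in by_id_a]
    missing += [gid for _, gid in id_pairs if gid not in by_id_b]
    if missing:
        raise ValueError(f"ortholog table references unknown genes: {sorted(set(missing))}")
    pairs = []
    for gid_a, gid_b in id_pairs:
        ga, gb = by_id_a[gid_a], by_id_b[gid_b]
        prot_a = _protein_of(ga, genome_a)
        prot_b = _protein_of(gb, genome_b)
        pairs.append(OrthologPair(ga, gb, align_proteins(prot_a, prot_b)))
    return pairs


def _protein_of(gene: GeneAnnotation, genome: GenomeSequence) -> str:
    cds = genome.fetch(gene.start, gene.end, gene.strand)
    cds = cds[: len(cds) - len(cds) % 3]
    return translate(cds)


def _genes_with_gtss(tus: list[TranscriptionalUnit]) -> dict:
    """gene_id -> the anchoring TSS of a gTU covering that gene."""
    out: dict[str, TSSRecord] = {}
    for tu in tus:
        if "g" not in tu.labels:
            continue
        for g in tu.member_genes:
            out.setdefault(g.gene_id, tu.tss)
    return out


def conserved_gtss(tus_a, tus_b, id_pairs) -> list[ConservationRecord]:
    """gTSS conservation by ortholog co-presence.

    A pair is conserved when each ortholog carries at least one gTSS in at
    least one condition; genes with a gTSS in exactly one strain yield
    strain-specific records. Orthologs without a gTSS in either strain
    produce no record.
    """
    with_a = _genes_with_gtss(tus_a)
    with_b = _genes_with_gtss(tus_b)
    records = []
    for gid_a, gid_b in id_pairs:
        tss_a = with_a.get(gid_a)
        tss_b = with_b.get(gid_b)
        if tss_a is None and tss_b is None:
            continue
        if tss_a is not None and tss_b is not None:
            verdict = "conserved"
        elif tss_a is not None:
            verdict = "strain_specific_a"
        else:
            verdict = "strain_specific_b"
        records.append(
            ConservationRecord("gTSS", verdict, gene_a=gid_a, gene_b=gid_b,
                               tss_a=tss_a, tss_b=tss_b,
                               evidence={"rule": "gene_co_presence"})
        )
    return records


def map_position_via_protein(pair: OrthologPair, position: int) -> tuple[int, bool]:
    """Project a genomic position inside gene_a to the expected genomic
    position in gene_b through the protein alignment.

    The position is converted to (codon index, within-codon offset) on the
    coding strand of gene_a, carried to the aligned residue of gene_b (a
    residue aligned to a gap falls back to the nearest aligned column and
    is flagged), and converted back. Returns (position_b, exact).
    """
    ga, gb = pair.gene_a, pair.gene_b
    if not ga.contains(position):
        raise ValueError(f"position {position} outside gene {ga.gene_id}")
    offset = position - ga.start if ga.strand == "+" else (ga.end - 1) - position
    codon, within = divmod(offset, 3)
    ib, exact = pair.alignment.b_for_a(codon)
    offset_b = ib * 3 + within
    if gb.strand == "+":
        pos_b = gb.start + offset_b
    else:
        pos_b = (gb.end - 1) - offset_b
    return pos_b, exact


def _class_tss_in_gene(tss_records, gene: GeneAnnotation, tss_class: str):
    """TSSs of a class lying within a gene body (sense for iTSS, antisense
    for aTSS)."""
    want_same_strand = tss_class == "iTSS"
    out = []
    for t in tss_records:
        if tss_class not in t.classes:
            continue
        if not gene.contains(t.position):
            continue
        same = t.strand == gene.strand
        if same == want_same_strand:
            out.append(t)
    return out


def conserved_internal_antisense_tss(tss_a, tss_b, pairs: list[OrthologPair],
                                     tss_class: str,
                                     th: Thresholds | None = None) -> list[ConservationRecord]:
    """aTSS/iTSS conservation: protein-alignment-mapped offset <= 10 nt.

    Within each ortholog pair, every strain-a TSS of the class is matched
    to the nearest unmatched strain-b TSS (ties to the lower coordinate);
    the pair is conserved when the observed position differs from the
    mapped expected position by at most the offset threshold.
    """
    th = th or Thresholds()
    if tss_class not in ("aTSS", "iTSS"):
        raise ValueError("class must be aTSS or iTSS")
    records = []
    for pair in pairs:
        in_a = _class_tss_in_gene(tss_a, pair.gene_a, tss_class)
        in_b = _class_tss_in_gene(tss_b, pair.gene_b, tss_class)
        if not in_a and not in_b:
            continue
        unmatched_b = list(in_b)
        for t in sorted(in_a, key=lambda t: t.position):
            expected, exact = map_position_via_protein(pair, t.position)
            best = None
            for u in sorted(unmatched_b, key=lambda u: u.position):
                offset = abs(u.position - expected)
                if best is None or offset < best[0]:
                    best = (offset, u)
            if best is not None and best[0] <= th.ortholog_tss_offset_max:
                unmatched_b.remove(best[1])
                records.append(
                    ConservationRecord(tss_class, "conserved",
                                       gene_a=pair.gene_a.gene_id,
                                       gene_b=pair.gene_b.gene_id,
                                       tss_a=t, tss_b=best[1],
                                       evidence={"offset_nt": int(best[0]),
                                                 "mapping_exact": exact})
                )
            else:
                records.append(
                    ConservationRecord(tss_class, "strain_specific_a",
                                       gene_a=pair.gene_a.gene_id,
                                       gene_b=pair.gene_b.gene_id, tss_a=t,
                                       evidence={"expected_position_b": int(expected)})
                )
        for u in unmatched_b:
            records.append(
                ConservationRecord(tss_class, "strain_specific_b",
                                   gene_a=pair.gene_a.gene_id,
                                   gene_b=pair.gene_b.gene_id, tss_b=u)
            )
    return records


def conserved_ntss(ntus_a: list[TranscriptionalUnit], genome_a: GenomeSequence,
                   genome_b: GenomeSequence, tus_b: list[TranscriptionalUnit],
                   th: Thresholds | None = None,
                   align_params: LocalAlignParams | None = None,
                   index_b: dict | None = None) -> list[ConservationRecord]:
    """nTSS conservation by sequence search against the partner genome.

    A free-standing transcript is conserved when its best hit passes the
    e-value and query-coverage cut-offs; the hit interval is then checked
    against the partner's TU catalog to distinguish "conserved as nTU"
    from "conserved but classified differently".
    """
    th = th or Thresholds()
    align_params = align_params or LocalAlignParams()
    partner_ntus = [tu for tu in tus_b if tu.labels == ("n",)]
    records = []
    for tu in ntus_a:
        seq = genome_a.fetch(tu.start, tu.end, tu.strand)
        if len(seq) < align_params.word_size or set(seq) <= {"N"}:
            records.append(ConservationRecord("nTSS", "strain_specific_a",
                                              tss_a=tu.tss,
                                              evidence={"tu_id": tu.tu_id,
                                                        "reason": "degenerate_query"}))
            continue
        hits = local_align_search(seq, genome_b.residues, align_params, index=index_b)
        best = hits[0] if hits else None
        evidence = {"tu_id": tu.tu_id}
        if best is not None:
            evidence.update(evalue=best.evalue, qcov=best.qcov,
                            hit_start=best.s_start, hit_end=best.s_end,
                            hit_strand=best.strand)
        if (best is None or best.evalue > th.ntss_evalue_max
                or best.qcov < th.ntss_qcov_min):
            records.append(ConservationRecord("nTSS", "strain_specific_a",
                                              tss_a=tu.tss, evidence=evidence))
            continue
        as_ntu = any(
            min(p.end, best.s_end) - max(p.start, best.s_start) > 0
            for p in partner_ntus
        )
        verdict = "conserved" if as_ntu else "conserved_classified_differently"
        records.append(ConservationRecord("nTSS", verdict, tss_a=tu.tss,
                                          evidence=evidence))
    return records


MINUS10_RANGE = (-12, -7)  # inclusive, relative to the TSS (+1 = TSS)


def _upstream_window(genome: GenomeSequence, position: int, strand: str,
                     window: int) -> str:
    """The ``window`` nt immediately upstream of the TSS, 5'->3'."""
    if strand == "+":
        return genome.residues[max(0, position - window): position]
    return revcomp(genome.residues[position + 1: position + 1 + window])


def promoter_divergence(tss: TSSRecord, genome_own: GenomeSequence,
                        genome_other: GenomeSequence, window: int = 50,
                        align_params: LocalAlignParams | None = None,
                        index_other: dict | None = None) -> PromoterReport:
    """Compare the promoter of a strain-specific TSS with its homologous
    locus in the partner genome.

    The upstream window is located in the partner by local sequence search,
    both windows are globally aligned, and every mismatch is reported with
    its position relative to the TSS; mismatches falling into the −10
    hexamer (−12..−7) are flagged.
    """
    align_params = align_params or LocalAlignParams()
    win_a = _upstream_window(genome_own, tss.position, tss.strand, window)
    if len(win_a) < align_params.word_size or set(win_a) <= {"N"}:
        return PromoterReport(tss, "unalignable", window_a=win_a)
    hits = local_align_search(win_a, genome_other.residues, align_params,
                              index=index_other)
    if not hits or hits[0].evalue > 1e-3:
        return PromoterReport(tss, "unalignable", window_a=win_a)
    best = hits[0]
    # extend the hit to the full query extent on the hit strand
    if best.strand == "+":
        s0 = best.s_start - best.q_start
        s1 = best.s_end + (len(win_a) - best.q_end)
        win_b = genome_other.residues[max(0, s0): s1]
    else:
        s0 = best.s_start - (len(win_a) - best.q_end)
        s1 = best.s_end + best.q_start
        win_b = revcomp(genome_other.residues[max(0, s0): s1])
    columns = align_windows_global(win_a, win_b)
    mismatches = []
    a_index = 0
    for base_a, base_b in columns:
        if base_a != "-":
            rel = a_index - len(win_a)  # -window .. -1 relative to TSS
            if base_b != base_a:
                mismatches.append((rel, base_a, base_b))
            a_index += 1
        elif base_b != "-":
            # insertion in the partner window, reported at the preceding column
            mismatches.append((a_index - len(win_a), "-", base_b))
    lo, hi = MINUS10_RANGE
    minus10_a = win_a[len(win_a) + lo: len(win_a) + hi + 1]
    b_by_rel = {}
    a_index = 0
    for base_a, base_b in columns:
        if base_a != "-":
            b_by_rel[a_index - len(win_a)] = base_b
            a_index += 1
    minus10_b = "".join(b_by_rel.get(rel, "-") for rel in range(lo, hi + 1))
    in_minus10 = [m for m in mismatches if lo <= m[0] <= hi]
    return PromoterReport(
        tss, "ok", window_a=win_a, window_b=win_b, mismatches=mismatches,
        minus10_a=minus10_a, minus10_b=minus10_b,
        minus10_mismatch=bool(in_minus10),
    )
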