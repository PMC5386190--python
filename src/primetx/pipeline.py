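"""End-to-end orchestration: per-strain analysis and the two-strain comparison.

``run_single`` executes the per-strain stages in order — scale, call
primary positions, correct, build the TSS set, segment TUs, classify,
UTRs/leaderless, UEF — and ``run_compare`` layers the comparative stages on
top: ortholog protein alignments, per-class TSS conservation, expression
clustering and FC correlation, actuaton detection, and promoter-divergence
reports for strain-specific gTSSs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import tss as tss_mod
from .actuaton import ActuatonCall, detect_actuatons
from .alignment import LocalAlignParams, build_word_index
from .conservation import (
    ConservationRecord,
    PromoterReport,
    build_ortholog_pairs,
    conserved_gtss,
    conserved_internal_antisense_tss,
    conserved_ntss,
    promoter_divergence,
)
from .expression import cluster_ortholog_profiles, pairwise_fc_correlation, uef
from .io import (
    read_annotation,
    read_genome,
    read_ortholog_table,
    read_track,
    write_table,
)
from .model import (
    ActuatonParams,
    CONDITIONS,
    GeneAnnotation,
    GenomeSequence,
    Library,
    SegmentationParams,
    Thresholds,
    TranscriptionalUnit,
)
from .tu import build_tus, classify_tus, compute_utrs, detect_leaderless

__all__ = [
    "StrainInputs",
    "SingleResult",
    "CompareResult",
    "load_strain_inputs",
    "run_single",
    "run_compare",
    "tss_table",
    "tu_table",
    "uef_table",
]

_STRAND_NAME = {"+": "fwd", "-": "rev"}


@dataclass
class StrainInputs:
    strain_id: str
    genome: GenomeSequence
    genes: list
    libraries: list  # 10 treated + 1 untreated


@dataclass
class SingleResult:
    strain_id: str
    genome: GenomeSequence
    genes: list
    normalized: list
    untreated: Library
    tss_records: list
    tus: list
    leaderless: list
    uefs: list


@dataclass
class CompareResult:
    ortholog_pairs: list
    gtss_records: list
    atss_records: list
    itss_records: list
    ntss_records_a: list
    ntss_records_b: list
    cluster_labels: tuple
    same_cluster_fraction: float
    fc_r2: float
    scatter: pd.DataFrame
    actuatons: dict  # strain -> [ActuatonCall]
    promoter_reports: dict  # strain -> [PromoterReport]
    summary: dict = field(default_factory=dict)


def load_strain_inputs(fixture_dir, strain: str) -> StrainInputs:
    """Read one strain's inputs from a fixture directory.

    Layout: ``{strain}.fasta``, ``{strain}.gff3``, ``libraries.tsv`` and
    ``tracks/{strain}.{condition}.{semantics}.{fwd|rev}.bedgraph``. A
    missing file aborts naming the path.
    """
    fixture_dir = Path(fixture_dir)
    genome = read_genome(fixture_dir / f"{strain}.fasta", strain_id=strain)
    genes = read_annotation(fixture_dir / f"{strain}.gff3")
    manifest = pd.read_csv(fixture_dir / "libraries.tsv", sep="\t")
    manifest = manifest[manifest["strain"] == strain]
    libraries = []
    for _, row in manifest.iterrows():
        cond = row["condition"]
        tracks = {}
        for sem in ("read_starts", "coverage"):
            for s in "+-":
                path = fixture_dir / "tracks" / f"{strain}.{cond}.{sem}.{_STRAND_NAME[s]}.bedgraph"
                if not path.exists():
                    raise FileNotFoundError(f"missing track file: {path}")
                tracks[(sem, s)] = read_track(path, len(genome), strain_id=strain,
                                              seq_id=genome.seq_id, strand=s,
                                              semantics=sem)
        libraries.append(Library(f"{strain}_{cond}", cond, bool(row["treated"]),
                                 tracks, float(row["raw_total"])))
    return StrainInputs(strain, genome, genes, libraries)


def run_single(inputs: StrainInputs, th: Thresholds | None = None,
               seg: SegmentationParams | None = None) -> SingleResult:
    th = th or Thresholds()
    seg = seg or SegmentationParams()
    treated = [lib for lib in inputs.libraries if lib.treated]
    untreated = [lib for lib in inputs.libraries if not lib.treated]
    if len(untreated) != 1:
        raise ValueError(
            f"strain {inputs.strain_id}: expected exactly one untreated library, "
            f"found {len(untreated)}"
        )
    missing = set(CONDITIONS) - {lib.condition for lib in treated}
    if missing:
        raise ValueError(f"strain {inputs.strain_id}: missing treated libraries "
                         f"for conditions {sorted(missing)}")
    normalized = tss_mod.normalize_libraries(treated, th)
    untreated_scaled = tss_mod.scale_library(untreated[0], th.scale_target)
    tss_records = tss_mod.build_tss_set(normalized, inputs.strain_id,
                                        inputs.genome.seq_id)
    coverage = {s: untreated_scaled.track("coverage", s) for s in "+-"}
    tus = build_tus(tss_records, coverage, inputs.strain_id, seg)
    classify_tus(tus, inputs.genes, th)
    for tu in tus:
        compute_utrs(tu)
    leaderless = detect_leaderless(tss_records, inputs.genes, th)
    uefs = [uef(tu.expression, tu_id=tu.tu_id, th=th) for tu in tus]
    return SingleResult(inputs.strain_id, inputs.genome, inputs.genes,
                        normalized, untreated_scaled, tss_records, tus,
                        leaderless, uefs)


def _gtu_profiles(result: SingleResult) -> dict:
    """gene_id -> expression vector of the gTU covering the gene."""
    out = {}
    for tu in result.tus:
        if "g" not in tu.labels:
            continue
        for g in tu.member_genes:
            out.setdefault(g.gene_id, tu.expression)
    return out


def run_compare(res_a: SingleResult, res_b: SingleResult, ortholog_ids,
                th: Thresholds | None = None,
                act_params: ActuatonParams | None = None,
                align_params: LocalAlignParams | None = None,
                seed: int = 0) -> CompareResult:
    th = th or Thresholds()
    act_params = act_params or ActuatonParams()
    align_params = align_params or LocalAlignParams()
    pairs = build_ortholog_pairs(ortholog_ids, res_a.genes, res_b.genes,
                                 res_a.genome, res_b.genome)
    gtss_records = conserved_gtss(res_a.tus, res_b.tus, ortholog_ids)
    atss_records = conserved_internal_antisense_tss(res_a.tss_records,
                                                    res_b.tss_records, pairs,
                                                    "aTSS", th)
    itss_records = conserved_internal_antisense_tss(res_a.tss_records,
                                                    res_b.tss_records, pairs,
                                                    "iTSS", th)
    index_a = build_word_index(res_a.genome.residues, align_params.word_size)
    index_b = build_word_index(res_b.genome.residues, align_params.word_size)
    ntus_a = [tu for tu in res_a.tus if tu.labels == ("n",)]
    ntus_b = [tu for tu in res_b.tus if tu.labels == ("n",)]
    ntss_records_a = conserved_ntss(ntus_a, res_a.genome, res_b.genome,
                                    res_b.tus, th, align_params, index_b)
    ntss_records_b = conserved_ntss(ntus_b, res_b.genome, res_a.genome,
                                    res_a.tus, th, align_params, index_a)

    prof_a = _gtu_profiles(res_a)
    prof_b = _gtu_profiles(res_b)
    expressed = [(ga, gb) for ga, gb in ortholog_ids
                 if ga in prof_a and gb in prof_b]
    if len(expressed) >= th.kmeans_k:
        mat_a = np.vstack([prof_a[ga] for ga, _ in expressed])
        mat_b = np.vstack([prof_b[gb] for _, gb in expressed])
        labels_a, labels_b, same_fraction = cluster_ortholog_profiles(
            mat_a, mat_b, k=th.kmeans_k, seed=seed)
        fc_r2, scatter = pairwise_fc_correlation(mat_a, mat_b)
    else:
        labels_a = labels_b = np.array([], dtype=int)
        same_fraction, fc_r2 = float("nan"), float("nan")
        scatter = pd.DataFrame()

    actuatons = {}
    for res in (res_a, res_b):
        coverage = {s: res.untreated.track("coverage", s) for s in "+-"}
        actuatons[res.strain_id] = detect_actuatons(res.tus, res.tss_records,
                                                    res.genes, coverage,
                                                    act_params)

    promoter_reports = {"A_side": [], "B_side": []}
    for rec in gtss_records:
        if rec.verdict == "strain_specific_a" and rec.tss_a is not None:
            promoter_reports["A_side"].append(
                promoter_divergence(rec.tss_a, res_a.genome, res_b.genome,
                                    align_params=align_params, index_other=index_b))
        elif rec.verdict == "strain_specific_b" and rec.tss_b is not None:
            promoter_reports["B_side"].append(
                promoter_divergence(rec.tss_b, res_b.genome, res_a.genome,
                                    align_params=align_params, index_other=index_a))

    summary = {
        "n_tus_a": len(res_a.tus),
        "n_tus_b": len(res_b.tus),
        "n_gtus_a": sum(1 for tu in res_a.tus if "g" in tu.labels),
        "n_gtus_b": sum(1 for tu in res_b.tus if "g" in tu.labels),
        "conserved_gtss": sum(1 for r in gtss_records if r.verdict == "conserved"),
        "conserved_atss": sum(1 for r in atss_records if r.verdict == "conserved"),
        "conserved_itss": sum(1 for r in itss_records if r.verdict == "conserved"),
        "conserved_ntss_a": sum(1 for r in ntss_records_a
                                if r.verdict.startswith("conserved")),
        "conserved_ntss_b": sum(1 for r in ntss_records_b
                                if r.verdict.startswith("conserved")),
        "same_cluster_fraction": same_fraction,
        "fc_r2": fc_r2,
        "n_actuatons_a": len(actuatons[res_a.strain_id]),
        "n_actuatons_b": len(actuatons[res_b.strain_id]),
        "n_leaderless_a": len(res_a.leaderless),
        "n_leaderless_b": len(res_b.leaderless),
    }
    return CompareResult(pairs, gtss_records, atss_records, itss_records,
                         ntss_records_a, ntss_records_b,
                         (labels_a, labels_b), same_fraction, fc_r2, scatter,
                         actuatons, promoter_reports, summary)


# ---------------------------------------------------------------------------
# result tables

def tss_table(tss_records) -> pd.DataFrame:
    rows = []
    for t in tss_records:
        row = {"strain": t.strain_id, "seq_id": t.seq_id,
               "position": t.position + 1, "strand": t.strand,
               "class": "/".join(t.classes)}
        for cond, value in zip(CONDITIONS, t.counts):
            row[cond] = value
        row["max_condition"] = t.max_condition
        rows.append(row)
    cols = ["strain", "seq_id", "position", "strand", "class",
            *CONDITIONS, "max_condition"]
    return pd.DataFrame(rows, columns=cols)


def tu_table(tus, uefs=None) -> pd.DataFrame:
    uef_by_id = {u.tu_id: u for u in (uefs or [])}
    rows = []
    for tu in tus:
        row = {"tu_id": tu.tu_id, "labels": tu.label_str,
               "seq_id": tu.seq_id, "start": tu.start + 1, "end": tu.end,
               "strand": tu.strand,
               "member_genes": ",".join(g.gene_id for g in tu.member_genes),
               "utr5": "" if tu.utr5_len is None else tu.utr5_len,
               "utr3": "" if tu.utr3_len is None else tu.utr3_len}
        for cond, value in zip(CONDITIONS, tu.expression):
            row[cond] = value
        row["max_condition"] = tu.tss.max_condition
        u = uef_by_id.get(tu.tu_id)
        row["uef"] = "" if u is None or u.undefined else u.uef
        rows.append(row)
    cols = ["tu_id", "labels", "seq_id", "start", "end", "strand",
            "member_genes", "utr5", "utr3", *CONDITIONS, "max_condition", "uef"]
    return pd.DataFrame(rows, columns=cols)


def uef_table(uefs) -> pd.DataFrame:
    rows = [{"tu_id": u.tu_id,
             "uef": "" if u.undefined else u.uef,
             "top_condition": u.top_condition or "",
             "second_condition": u.second_condition or "",
             "high": u.high}
            for u in uefs]
    df = pd.DataFrame(rows, columns=["tu_id", "uef", "top_condition",
                                     "second_condition", "high"])
    # ranked by maximum UEF, undefined entries last
    key = pd.to_numeric(df["uef"], errors="coerce")
    return df.assign(_k=key).sort_values(["_k", "tu_id"], ascending=[False, True],
                                         na_position="last").drop(columns="_k")


def conservation_table(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "class": r.tss_class, "verdict": r.verdict,
            "gene_a": r.gene_a or "", "gene_b": r.gene_b or "",
            "position_a": "" if r.tss_a is None else r.tss_a.position + 1,
            "position_b": "" if r.tss_b is None else r.tss_b.position + 1,
            "evidence": ";".join(f"{k}={v}" for k, v in sorted(r.evidence.items())),
        })
    return pd.DataFrame(rows, columns=["class", "verdict", "gene_a", "gene_b",
                                       "position_a", "position_b", "evidence"])


def actuaton_table(calls, strain: str) -> pd.DataFrame:
    rows = [{"strain": strain, "tu_id": c.tu_id,
             "srna_start": c.srna_start + 1, "srna_end": c.srna_end,
             "downstream_gene": c.downstream_gene,
             "drop_ratio": round(c.drop_ratio, 4),
             "readthrough_fraction": round(c.readthrough_fraction, 4),
             "abundance_percentile": round(c.srna_abundance_rank, 1),
             "flags": ",".join(c.flags)}
            for c in calls]
    return pd.DataFrame(rows, columns=["strain", "tu_id", "srna_start", "srna_end",
                                       "downstream_gene", "drop_ratio",
                                       "readthrough_fraction",
                                       "abundance_percentile", "flags"])


def write_single_outputs(result: SingleResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(tss_table(result.tss_records),
                outdir / f"{result.strain_id}.tss.tsv")
    write_table(tu_table(result.tus, result.uefs),
                outdir / f"{result.strain_id}.tu.tsv")
    write_table(uef_table(result.uefs), outdir / f"{result.strain_id}.uef.tsv")
    write_table([{"gene_id": g.gene_id} for g in result.leaderless],
                outdir / f"{result.strain_id}.leaderless.tsv",
                columns=["gene_id"])


def write_compare_outputs(result: CompareResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(conservation_table(result.gtss_records), outdir / "conserved_gtss.tsv")
    write_table(conservation_table(result.atss_records), outdir / "conserved_atss.tsv")
    write_table(conservation_table(result.itss_records), outdir / "conserved_itss.tsv")
    write_table(conservation_table(result.ntss_records_a + result.ntss_records_b),
                outdir / "conserved_ntss.tsv")
    write_table(result.scatter, outdir / "fc_scatter.tsv")
    for strain, calls in result.actuatons.items():
        write_table(actuaton_table(calls, strain), outdir / f"actuatons_{strain}.tsv")
    rows = []
    for side, reports in result.promoter_reports.items():
        for rep in reports:
            rows.append({
                "side": side, "position": rep.tss.position + 1,
                "strand": rep.tss.strand, "verdict": rep.verdict,
                "window_own": rep.window_a, "window_other": rep.window_b,
                "minus10_own": rep.minus10_a, "minus10_other": rep.minus10_b,
                "minus10_mismatch": rep.minus10_mismatch,
                "n_mismatches": len(rep.mismatches),
            })
    write_table(rows, outdir / "promoter_reports.tsv",
                columns=["side", "position", "strand", "verdict", "window_own",
                         "window_other", "minus10_own", "minus10_other",
                         "minus10_mismatch", "n_mismatches"])
    write_table([{"metric": k, "value": v} for k, v in result.summary.items()],
                outdir / "summary.tsv", columns=["metric", "value"])
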