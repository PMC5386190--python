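"""Readers and writers for the standard formats the pipeline touches.

FASTA (genomes), GFF3 (gene annotation, 1-based inclusive), bedGraph
(strand-specific tracks, 0-based half-open, one file per strand per
semantics), and TSV for every result table. bedGraph intervals are
converted to dense per-position vectors on read; positions not covered by
any interval are zero.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence
from urllib.parse import unquote

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import GeneAnnotation, GenomeSequence, Track, to_internal

__all__ = [
    "read_genome",
    "write_genome",
    "read_annotation",
    "write_annotation",
    "read_track",
    "write_track",
    "write_table",
    "read_ortholog_table",
    "write_ortholog_table",
]

#: GFF3 feature types treated as gene-level records.
_GENE_FEATURES = {"gene", "sRNA", "ncRNA"}


def read_genome(path, strain_id: str | None = None) -> GenomeSequence:
    """Read a single-record FASTA genome."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    return GenomeSequence(
        strain_id=strain_id or rec.id,
        seq_id=rec.id,
        residues=str(rec.seq).upper(),
    )


def write_genome(genome: GenomeSequence, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.seq_id}\n")
        for i in range(0, len(genome.residues), 70):
            fh.write(genome.residues[i : i + 70] + "\n")


def _parse_gff_attributes(text: str) -> dict:
    attrs = {}
    for item in text.strip().rstrip(";").split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = unquote(value.strip())
    return attrs


def read_annotation(path) -> list[GeneAnnotation]:
    """Parse gene-level features from a GFF3 file.

    Coordinates are converted from GFF3's 1-based inclusive convention to
    internal 0-based half-open. Malformed lines raise with their line
    number; duplicate gene IDs are an error.
    """
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}")
            seq_id, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
            if ftype not in _GENE_FEATURES:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            attrs = _parse_gff_attributes(attr_s)
            gene_id = attrs.get("ID") or attrs.get("locus_tag")
            if not gene_id:
                raise ValueError(f"{path}:{lineno}: feature without ID attribute")
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            start, end = to_internal(start1, end1)
            kind = attrs.get("gene_biotype", "protein_coding")
            if ftype in ("sRNA", "ncRNA") or kind in ("sRNA", "ncRNA", "known_sRNA"):
                kind = "known_sRNA"
            elif kind != "protein_coding":
                kind = "other"
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    seq_id=seq_id,
                    start=start,
                    end=end,
                    strand=strand,
                    kind=kind,
                    product=attrs.get("product", ""),
                )
            )
    return genes


def write_annotation(genes: Sequence[GeneAnnotation], path) -> None:
    """Write gene-level features as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            ftype = "sRNA" if g.kind == "known_sRNA" else "gene"
            attrs = f"ID={g.gene_id};gene_biotype={g.kind}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                "\t".join(
                    [g.seq_id, "primetx", ftype, str(g.start + 1), str(g.end),
                     ".", g.strand, ".", attrs]
                )
                + "\n"
            )


def read_track(path, genome_length: int, *, strain_id: str = "", seq_id: str = "",
               strand: str = "+", semantics: str = "read_starts") -> Track:
    """Read a bedGraph file into a dense per-position vector.

    bedGraph intervals are 0-based half-open. Intervals beyond the genome
    end and negative values are errors.
    """
    values = np.zeros(genome_length, dtype=float)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph fields")
            chrom, start_s, end_s, value_s = fields
            start, end, value = int(start_s), int(end_s), float(value_s)
            if end > genome_length:
                raise ValueError(
                    f"{path}:{lineno}: interval end {end} exceeds genome length {genome_length}"
                )
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}..{end}")
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative value {value}")
            values[start:end] = value
            if not seq_id:
                seq_id = chrom
    return Track(strain_id=strain_id, seq_id=seq_id or "chr", strand=strand,
                 values=values, semantics=semantics)


def write_track(track: Track, path) -> None:
    """Write a dense track as run-length-encoded bedGraph (zeros omitted)."""
    v = track.values
    with open(path, "w") as fh:
        # boundaries of constant runs
        change = np.flatnonzero(np.diff(v)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(v)]))
        for s, e in zip(starts, ends):
            val = v[s]
            if val == 0:
                continue
            fh.write(f"{track.seq_id}\t{s}\t{e}\t{val:g}\n")


def write_table(records: pd.DataFrame | Iterable[dict], path, columns: Sequence[str] | None = None) -> None:
    """Write records as a deterministic, byte-reproducible TSV.

    Column order is taken from ``columns`` when given, otherwise from the
    frame/first record. Floats are rendered with repr-shortest formatting so
    identical input yields identical bytes.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records))
    if columns is not None:
        if len(records) == 0:
            records = pd.DataFrame(columns=list(columns))
        else:
            records = records[list(columns)]
    records.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_ortholog_table(path) -> list[tuple[str, str]]:
    """Read the two-column TSV of ortholog gene-ID pairs (with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: ortholog table needs two columns")
    return list(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_ortholog_table(pairs: Sequence[tuple[str, str]], path,
                         names: tuple[str, str] = ("gene_a", "gene_b")) -> None:
    write_table(pd.DataFrame(pairs, columns=list(names)), path)
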