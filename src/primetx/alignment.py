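"""Sequence alignment engines used by the conservation analyses.

Three layers:

* global protein alignment (Needleman–Wunsch, BLOSUM62, gap open 11 /
  extend 1 in NCBI cost convention) for mapping TSS positions between
  orthologous genes through the encoded amino-acid sequence;
* an exact affine-gap local alignment (Smith–Waterman scoring: match +2,
  mismatch −3, gap open 5 / extend 2) used directly on small problems;
* a word-seeded local search over whole genomes that clusters exact 11-mer
  seed hits by diagonal and refines each candidate window with the same
  local scoring, reporting Karlin–Altschul E-values computed from the
  scoring scheme under uniform base composition.

The dynamic programming itself is delegated to Biopython's
``PairwiseAligner`` (C implementation); seeding, windowing and the E-value
statistics are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import exp, gcd, log

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

from .model import revcomp

__all__ = [
    "ProteinAlignment",
    "LocalHit",
    "LocalAlignParams",
    "align_proteins",
    "local_align",
    "local_align_search",
    "karlin_altschul_params",
    "align_windows_global",
]


# ---------------------------------------------------------------------------
# protein global alignment

@dataclass
class ProteinAlignment:
    seq_a: str
    seq_b: str
    score: float
    pairs: list  # aligned residue index pairs (ia, ib), gap-free columns only
    percent_identity: float

    def b_for_a(self, ia: int) -> tuple[int, bool]:
        """Residue index in b aligned to residue ia of a.

        For a residue aligned to a gap, the nearest aligned column is used
        and the second element is False (flagging the approximation).
        """
        exact = self._a_to_b().get(ia)
        if exact is not None:
            return exact, True
        if not self.pairs:
            raise ValueError("empty alignment")
        nearest = min(self.pairs, key=lambda p: (abs(p[0] - ia), p[0]))
        return nearest[1], False

    def _a_to_b(self) -> dict:
        if not hasattr(self, "_map_ab"):
            self._map_ab = {ia: ib for ia, ib in self.pairs}
        return self._map_ab


@lru_cache(maxsize=1)
def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # NCBI convention: a gap of length k costs 11 + k
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


def align_proteins(seq_a: str, seq_b: str) -> ProteinAlignment:
    """Global alignment of two amino-acid sequences (first optimum kept,
    which fixes tie-breaking deterministically)."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty protein sequence")
    seq_a = seq_a.rstrip("*")
    seq_b = seq_b.rstrip("*")
    aln = _protein_aligner().align(seq_a, seq_b)[0]
    pairs = []
    matches = 0
    for (qs, qe), (ss, se) in zip(*aln.aligned):
        for off in range(qe - qs):
            ia, ib = qs + off, ss + off
            pairs.append((ia, ib))
            if seq_a[ia] == seq_b[ib]:
                matches += 1
    columns = max(len(pairs), 1)
    return ProteinAlignment(seq_a, seq_b, float(aln.score), pairs,
                            100.0 * matches / columns)


# ---------------------------------------------------------------------------
# local nucleotide alignment and statistics

@dataclass(frozen=True)
class LocalAlignParams:
    word_size: int = 11
    match: int = 2
    mismatch: int = -3
    gap_open: int = 5   # NCBI convention: gap of length k costs open + k*extend
    gap_extend: int = 2
    max_windows: int = 50
    direct_cell_limit: int = 250_000  # below this, skip seeding and run full DP


@dataclass
class LocalHit:
    score: float
    evalue: float
    qcov: float
    q_start: int
    q_end: int
    s_start: int  # forward-strand subject coordinates, 0-based half-open
    s_end: int
    strand: str
    identity: float


def karlin_altschul_params(params: LocalAlignParams) -> tuple[float, float, float]:
    """Ungapped (lambda, K, H) for the match/mismatch scheme under uniform
    base composition, via the lattice-case Spitzer series."""
    probs = {params.match: 0.25, params.mismatch: 0.75}
    lam = brentq(lambda l: sum(p * exp(l * s) for s, p in probs.items()) - 1.0,
                 1e-6, 10.0)
    h = lam * sum(s * p * exp(lam * s) for s, p in probs.items())
    delta = gcd(abs(params.match), abs(params.mismatch))
    step = np.zeros(params.match - params.mismatch + 1)
    for s, p in probs.items():
        step[s - params.mismatch] = p
    dist = np.array([1.0])
    offset = 0
    sigma = 0.0
    for k in range(1, 400):
        dist = np.convolve(dist, step)
        offset += params.mismatch
        values = np.arange(len(dist)) + offset
        neg = values < 0
        term = dist[~neg].sum() + (dist[neg] * np.exp(lam * values[neg])).sum()
        sigma += term / k
        if term / k < 1e-12:
            break
    K = delta * lam * exp(-2.0 * sigma) / (h * (1.0 - exp(-lam * delta)))
    return lam, K, h


@lru_cache(maxsize=8)
def _ka_cached(word_size, match, mismatch, gap_open, gap_extend, max_windows, limit):
    return karlin_altschul_params(LocalAlignParams(word_size, match, mismatch,
                                                   gap_open, gap_extend,
                                                   max_windows, limit))


@lru_cache(maxsize=8)
def _local_aligner(match: int, mismatch: int, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    alphabet = "ACGTN"
    matrix = substitution_matrices.Array(alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            # N is ambiguous and scores as a mismatch against everything
            matrix[x, y] = match if (x == y and x != "N") else mismatch
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align(query: str, subject: str, params: LocalAlignParams | None = None):
    """Best local alignment of query vs subject (forward orientations).

    Returns (score, q_start, q_end, s_start, s_end, aligned_query_positions,
    identity) or None when no positive-scoring alignment exists.
    """
    params = params or LocalAlignParams()
    aligner = _local_aligner(params.match, params.mismatch,
                             params.gap_open, params.gap_extend)
    alignments = aligner.align(query, subject)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    aln = alignments[0]
    blocks_q, blocks_s = aln.aligned
    if len(blocks_q) == 0:
        return None
    aligned_q = int(sum(qe - qs for qs, qe in blocks_q))
    matches = 0
    for (qs, qe), (ss, se) in zip(blocks_q, blocks_s):
        for off in range(qe - qs):
            if query[qs + off] == subject[ss + off] and query[qs + off] != "N":
                matches += 1
    q_start, q_end = int(blocks_q[0][0]), int(blocks_q[-1][1])
    s_start, s_end = int(blocks_s[0][0]), int(blocks_s[-1][1])
    identity = matches / max(aligned_q, 1)
    return float(aln.score), q_start, q_end, s_start, s_end, aligned_q, identity


def _seed_windows(query: str, subject: str, params: LocalAlignParams,
                  index: dict | None) -> list[tuple[int, int]]:
    """Candidate subject windows from clustered exact word matches."""
    w = params.word_size
    if index is None:
        index = build_word_index(subject, w)
    hits = []  # (diagonal, s_pos)
    for q in range(len(query) - w + 1):
        word = query[q : q + w]
        if "N" in word:
            continue
        for s in index.get(word, ()):
            hits.append((s - q, s))
    if not hits:
        return []
    hits.sort()
    clusters: list[list[tuple[int, int]]] = []
    for d, s in hits:
        if clusters and d - clusters[-1][-1][0] <= 30:
            clusters[-1].append((d, s))
        else:
            clusters.append([(d, s)])
    windows = []
    pad = len(query) + 30
    for cl in clusters[: params.max_windows]:
        smin = min(s for _, s in cl)
        smax = max(s for _, s in cl)
        windows.append((max(0, smin - pad), min(len(subject), smax + pad)))
    # merge overlapping windows
    windows.sort()
    merged = [windows[0]]
    for a, b in windows[1:]:
        if a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def build_word_index(subject: str, word_size: int) -> dict:
    """Exact-word index of a subject sequence (reusable across queries)."""
    index: dict[str, list[int]] = {}
    for i in range(len(subject) - word_size + 1):
        word = subject[i : i + word_size]
        if "N" in word:
            continue
        index.setdefault(word, []).append(i)
    return index


def local_align_search(query: str, subject: str,
                       params: LocalAlignParams | None = None,
                       index: dict | None = None,
                       index_rc: dict | None = None) -> list[LocalHit]:
    """Search a query against both strands of a subject genome.

    Small problems are solved with a single full local alignment; large
    subjects go through exact-word seeding first. E-values follow
    E = K * m * n * exp(-lambda * S) with m the query length and n the
    doubled subject length (both strands searched). Hits are returned
    sorted by score, best first.
    """
    params = params or LocalAlignParams()
    if len(query) < params.word_size:
        raise ValueError(f"query shorter than the word size ({params.word_size})")
    if set(query) <= {"N"}:
        return []
    lam, K, _ = _ka_cached(params.word_size, params.match, params.mismatch,
                           params.gap_open, params.gap_extend,
                           params.max_windows, params.direct_cell_limit)
    m, n_eff = len(query), 2 * len(subject)
    hits: list[LocalHit] = []

    def add_hit(result, window_start: int, strand: str):
        score, q_start, q_end, s_start, s_end, aligned_q, identity = result
        s_start += window_start
        s_end += window_start
        if strand == "-":
            # coordinates were computed on the reversed query; flip back
            q_start, q_end = len(query) - q_end, len(query) - q_start
        hits.append(
            LocalHit(
                score=score,
                evalue=K * m * n_eff * exp(-lam * score),
                qcov=aligned_q / len(query),
                q_start=q_start,
                q_end=q_end,
                s_start=s_start,
                s_end=s_end,
                strand=strand,
                identity=identity,
            )
        )

    for strand, q in (("+", query), ("-", revcomp(query))):
        idx = index if strand == "+" else index_rc
        if len(q) * len(subject) <= params.direct_cell_limit:
            result = local_align(q, subject, params)
            if result is not None:
                add_hit(result, 0, strand)
            continue
        for ws, we in _seed_windows(q, subject, params, idx):
            result = local_align(q, subject[ws:we], params)
            if result is not None:
                add_hit(result, ws, strand)
    hits.sort(key=lambda h: (-h.score, h.s_start, h.strand))
    # drop duplicate window hits covering the same subject region
    deduped: list[LocalHit] = []
    for h in hits:
        if any(hd.strand == h.strand and
               min(hd.s_end, h.s_end) - max(hd.s_start, h.s_start) > 0
               for hd in deduped):
            continue
        deduped.append(h)
    return deduped


@lru_cache(maxsize=1)
def _global_nt_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    alphabet = "ACGTN"
    matrix = substitution_matrices.Array(alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            matrix[x, y] = 1 if (x == y and x != "N") else -1
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    return aligner


def align_windows_global(window_a: str, window_b: str) -> list[tuple[str, str]]:
    """Global nucleotide alignment of two short windows, returned as aligned
    column pairs (base_a, base_b) with '-' for gaps."""
    if not window_a or not window_b:
        raise ValueError("cannot align empty windows")
    aln = _global_nt_aligner().align(window_a, window_b)[0]
    a_row, b_row = str(aln[0]), str(aln[1])
    return list(zip(a_row, b_row))
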