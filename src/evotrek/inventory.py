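"""Homology inventory: all-vs-all protein alignment and family clustering.

Gene families are built without any external database: every protein is
compared against every other by exact Smith-Waterman local alignment with
affine gaps (BLOSUM62, gap open 11, extend 1 — the de facto protein-search
defaults), hits are filtered on a normalized bit-like score and query
coverage, and families are the connected components of the resulting hit
graph (single linkage, so inclusive families in the spirit of calling
slp5-8 all "slp").

An E-value cutoff presupposes a database size, so filtering instead uses
the database-size-free bit score computed with the gapped BLOSUM62/11/1
Karlin-Altschul parameters (lambda = 0.267, K = 0.041):
``bits = (lambda * S - ln K) / ln 2``.  The default thresholds are
bit score >= 50 and query coverage >= 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentHit",
    "GeneFamily",
    "smith_waterman",
    "bit_score",
    "find_homologs",
    "cluster_families",
    "build_matrix",
    "copy_number_table",
    "AlphabetError",
]

# gapped BLOSUM62, gap open 11 / extend 1 (Altschul et al. defaults)
KA_LAMBDA = 0.267
KA_K = 0.041

_AA = set("ACDEFGHIKLMNPQRSTVWYX")


class AlphabetError(ValueError):
    """Sequence contains a residue outside the 20-letter alphabet (+X)."""


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    mat = substitution_matrices.load(matrix_name)
    mat = mat.copy()
    # X is tolerated and scored 0 against everything
    if "X" in mat.alphabet:
        for a in mat.alphabet:
            mat["X", a] = 0.0
            mat[a, "X"] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = mat
    # BLAST convention: a gap of length k costs open + k * extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _check_protein(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _AA
    if bad:
        raise AlphabetError(f"invalid protein residues: {sorted(bad)}")
    return seq


@dataclass
class AlignmentHit:
    score: float
    span_a: tuple[int, int]  # [start, end) on a
    span_b: tuple[int, int]
    identity: float  # percent identical over aligned columns (incl. gap columns)
    coverage: float  # aligned span on a / len(a)


def bit_score(raw_score: float) -> float:
    """Normalized bit-like score from a raw Smith-Waterman score."""
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def smith_waterman(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> AlignmentHit:
    """Optimal local alignment of two protein sequences with affine gaps.

    Exact Smith-Waterman (no heuristics).  Returns the optimal score, the
    aligned spans on both sequences (0-based half-open), percent identity
    over aligned columns and query (``a``) coverage.  Empty input yields
    score 0 with empty spans.
    """
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    a, b = _check_protein(a), _check_protein(b)
    if not a or not b:
        return AlignmentHit(0.0, (0, 0), (0, 0), 0.0, 0.0)
    aligner = _aligner(matrix, gap_open, gap_extend)
    score = aligner.score(a, b)
    if score <= 0:
        return AlignmentHit(0.0, (0, 0), (0, 0), 0.0, 0.0)
    aln = aligner.align(a, b)[0]
    (a0, a1) = aln.aligned[0][0][0], aln.aligned[0][-1][1]
    (b0, b1) = aln.aligned[1][0][0], aln.aligned[1][-1][1]
    cols = 0
    matches = 0
    sa, sb = aln[0], aln[1]  # gapped alignment strings
    for x, y in zip(sa, sb):
        cols += 1
        if x == y and x != "-":
            matches += 1
    identity = 100.0 * matches / cols if cols else 0.0
    coverage = (a1 - a0) / len(a)
    return AlignmentHit(float(score), (a0, a1), (b0, b1), identity, coverage)


def self_score(seq: str, matrix: str = "BLOSUM62") -> float:
    """Sum of diagonal substitution-matrix entries over a sequence."""
    mat = _aligner(matrix, 11, 1).substitution_matrix
    return float(sum(mat[c, c] for c in _check_protein(seq)))


def find_homologs(
    queries: Mapping[str, str],
    db: Mapping[str, str],
    min_bit_like: float = 50.0,
    min_coverage: float = 0.5,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> pd.DataFrame:
    """All-vs-all exact Smith-Waterman search with threshold filtering.

    Returns a HitTable DataFrame with columns ``query, target, score,
    bit_score, identity, coverage`` containing all and only the pairs
    passing both thresholds.  Scoring is symmetric, so hit(a, b) appears
    iff hit(b, a) does, with equal raw score.  Self-pairs (same id) are
    skipped.
    """
    rows = []
    # raw score needed to reach the bit threshold; skip the (costly)
    # traceback for pairs that cannot pass
    min_raw = (min_bit_like * math.log(2.0) + math.log(KA_K)) / KA_LAMBDA
    aligner = _aligner(matrix, gap_open, gap_extend)
    qitems = list(queries.items())
    ditems = list(db.items())
    seqs = {k: _check_protein(v) for k, v in qitems + ditems}
    done: set[frozenset[str]] = set()
    for qid, _ in qitems:
        for tid, _ in ditems:
            if qid == tid:
                continue
            pair = frozenset((qid, tid))
            if pair in done:
                continue
            done.add(pair)
            q, t = seqs[qid], seqs[tid]
            if not q or not t:
                continue
            score = aligner.score(q, t)
            if score < min_raw:
                continue
            hit = smith_waterman(q, t, matrix, gap_open, gap_extend)
            cov_q = hit.coverage
            cov_t = (hit.span_b[1] - hit.span_b[0]) / len(t)
            for a, b, cov in ((qid, tid, cov_q), (tid, qid, cov_t)):
                if cov >= min_coverage:
                    rows.append(
                        {
                            "query": a,
                            "target": b,
                            "score": hit.score,
                            "bit_score": bit_score(hit.score),
                            "identity": hit.identity,
                            "coverage": cov,
                        }
                    )
    return pd.DataFrame(
        rows, columns=["query", "target", "score", "bit_score", "identity", "coverage"]
    )


@dataclass
class GeneFamily:
    family_id: str
    members: list[tuple[str, str]]  # (taxon, gene id)

    def taxa(self) -> set[str]:
        return {t for t, _ in self.members}


def cluster_families(
    hits: pd.DataFrame, gene_taxon: Mapping[str, str]
) -> list[GeneFamily]:
    """Single-linkage clustering of the hit graph into gene families.

    ``gene_taxon`` maps every gene id in the universe to its taxon; genes
    without hits become singleton families.  Families are numbered
    deterministically by their lexicographically smallest member id.
    """
    graph = nx.Graph()
    graph.add_nodes_from(gene_taxon)
    for q, t in zip(hits["query"], hits["target"]):
        if q not in gene_taxon or t not in gene_taxon:
            raise ValueError(f"hit references unknown gene: {q!r} or {t!r}")
        graph.add_edge(q, t)
    comps = sorted(nx.connected_components(graph), key=lambda c: min(c))
    families = []
    for i, comp in enumerate(comps, start=1):
        members = sorted((gene_taxon[g], g) for g in comp)
        families.append(GeneFamily(family_id=f"FAM{i:04d}", members=members))
    return families


def build_matrix(families: Sequence[GeneFamily], taxa: Sequence[str]) -> pd.DataFrame:
    """Binary presence/absence matrix (families x taxa).

    A cell is 1 iff the family has at least one member from that taxon
    (paralogs collapse to 1; see :func:`copy_number_table`).  Column order
    follows ``taxa``.
    """
    taxa = list(taxa)
    known = set(taxa)
    data = {}
    for fam in families:
        missing = fam.taxa() - known
        if missing:
            raise ValueError(
                f"family {fam.family_id} has members from unknown taxa {sorted(missing)}"
            )
        data[fam.family_id] = [1 if any(t == tx for t, _ in fam.members) else 0 for tx in taxa]
    mat = pd.DataFrame.from_dict(data, orient="index", columns=taxa, dtype="int8")
    if not len(mat):
        mat = pd.DataFrame(columns=taxa, dtype="int8")
    return mat


def copy_number_table(families: Sequence[GeneFamily], taxa: Sequence[str]) -> pd.DataFrame:
    """Per-taxon member counts (the paralog side table behind the binary matrix)."""
    taxa = list(taxa)
    data = {}
    for fam in families:
        counts = {tx: 0 for tx in taxa}
        for t, _ in fam.members:
            counts[t] += 1
        data[fam.family_id] = [counts[tx] for tx in taxa]
    cn = pd.DataFrame.from_dict(data, orient="index", columns=taxa, dtype="int64")
    if not len(cn):
        cn = pd.DataFrame(columns=taxa, dtype="int64")
    return cn
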