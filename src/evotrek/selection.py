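"""Pairwise dN/dS (Nei-Gojobori 1986 counting) on codon alignments.

For every pair of in-frame coding sequences the method counts synonymous
(S) and nonsynonymous (N) *sites* — each of a codon's nine single-nucleotide
neighbors carries weight 1/3; neighbors that are stop codons are dropped,
so a stop-adjacent codon contributes slightly fewer than 3 sites — and
synonymous/nonsynonymous *differences* (Sd, Nd) by averaging over all
orderings of the differing codon positions, excluding mutational pathways
that pass through a stop codon.  Proportions pS = Sd/S and pN = Nd/N are
Jukes-Cantor corrected, d = -(3/4) ln(1 - 4p/3), and the ratio dN/dS is
reported.  Ratios are *undefined* (never coerced to 0 or infinity) when
dS = 0, when the correction is out of domain (p >= 0.75), or when no codon
columns survive pairwise deletion.

Family-level selection is summarized as the arithmetic mean of the defined
pairwise ratios: > 1 positive (diversifying) selection, < 1 purifying,
== 1 boundary.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "CodonAlignment",
    "NGCounts",
    "DnDsResult",
    "backtranslate",
    "ng86_counts",
    "dnds_pair",
    "family_mean_dnds",
    "classify_selection",
    "translate_cds",
    "CODON_TABLE",
    "SENSE_CODONS",
    "STOP_CODONS",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # the standard genetic code
CODON_TABLE: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TABLE))
_NUCS = "ACGT"


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS (standard code); trailing stop stripped."""
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    out = []
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise ValueError(f"internal stop codon {c} at codon {i}")
        if c not in CODON_TABLE:
            raise ValueError(f"ambiguous or invalid codon {c!r} at codon {i}")
        out.append(CODON_TABLE[c])
    return "".join(out)


# ---------------------------------------------------------------------------
# NG86 per-codon machinery


@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one sense codon.

    Each of the nine single-nucleotide neighbors weighs 1/3; stop-codon
    neighbors are excluded, so S + N = 3 - stops/3.
    """
    if codon not in CODON_TABLE:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = CODON_TABLE[codon]
    syn = nonsyn = 0.0
    for pos in range(3):
        for nt in _NUCS:
            if nt == codon[pos]:
                continue
            nb = codon[:pos] + nt + codon[pos + 1 :]
            if nb in STOP_CODONS:
                continue
            if CODON_TABLE[nb] == aa:
                syn += 1.0 / 3.0
            else:
                nonsyn += 1.0 / 3.0
    return syn, nonsyn


@lru_cache(maxsize=None)
def _codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons by pathway averaging.

    All orderings of the differing positions are enumerated; pathways
    passing through a stop codon are excluded and the remainder averaged
    with equal weights.  If every pathway is blocked (guarded; cannot
    happen for sense endpoints under the standard code), all pathways are
    used with the stop treated as a distinct amino acid.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> Optional[tuple[float, float]]:
        syn = nonsyn = 0.0
        cur = codon_a
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            aa_cur = CODON_TABLE.get(cur, "*")
            aa_nxt = CODON_TABLE.get(nxt, "*")
            if aa_cur == aa_nxt:
                syn += 1.0
            else:
                nonsyn += 1.0
            cur = nxt
        return syn, nonsyn

    paths = [walk(order, False) for order in itertools.permutations(diff_pos)]
    valid = [p for p in paths if p is not None]
    if not valid:  # pragma: no cover - unreachable for standard-code sense pairs
        valid = [walk(order, True) for order in itertools.permutations(diff_pos)]
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    return sd, nd


@dataclass
class NGCounts:
    """NG86 site and difference tallies for one sequence pair."""

    S: float = 0.0
    N: float = 0.0
    Sd: float = 0.0
    Nd: float = 0.0
    codons: int = 0  # codon columns compared (after pairwise deletion)

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S > 0 else math.nan

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N > 0 else math.nan

    @staticmethod
    def _jc(p: float) -> float:
        if math.isnan(p) or p >= 0.75:
            return math.nan
        return -0.75 * math.log1p(-4.0 * p / 3.0)

    @property
    def dS(self) -> float:
        return self._jc(self.pS)

    @property
    def dN(self) -> float:
        return self._jc(self.pN)

    @property
    def ratio(self) -> float:
        """dN/dS; nan when undefined (dS == 0 or out-of-domain correction)."""
        ds, dn = self.dS, self.dN
        if math.isnan(ds) or math.isnan(dn) or ds == 0.0:
            return math.nan
        return dn / ds

    def __add__(self, other: "NGCounts") -> "NGCounts":
        return NGCounts(
            self.S + other.S,
            self.N + other.N,
            self.Sd + other.Sd,
            self.Nd + other.Nd,
            self.codons + other.codons,
        )


def ng86_counts(codon_a: str, codon_b: str) -> NGCounts:
    """NG86 contribution of a single codon site (pair of sense codons).

    Site counts are the average of the two codons' counts; differences are
    pathway-averaged.  Raises on stop-codon input.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c!r} is not a valid input")
        if c not in CODON_TABLE:
            raise ValueError(f"invalid codon {c!r}")
    sa, na = _codon_sites(codon_a)
    sb, nb = _codon_sites(codon_b)
    sd, nd = _codon_differences(codon_a, codon_b)
    return NGCounts(S=(sa + sb) / 2.0, N=(na + nb) / 2.0, Sd=sd, Nd=nd, codons=1)


# ---------------------------------------------------------------------------
# Alignment-level operations


@dataclass
class CodonAlignment:
    """In-frame aligned coding sequences; gaps only in whole-codon units."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("all rows must have equal length")
        if lengths and next(iter(lengths)) % 3:
            raise ValueError("alignment length must be a multiple of 3")
        for gid, row in zip(self.ids, self.rows):
            for i in range(0, len(row), 3):
                codon = row[i : i + 3]
                if "-" in codon and codon != "---":
                    raise ValueError(
                        f"{gid}: gap not in whole-codon units at codon {i // 3}"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0

    def row(self, gid: str) -> str:
        return self.rows[self.ids.index(gid)]


def backtranslate(
    protein_alignment: Mapping[str, str], cds_by_gene: Mapping[str, str]
) -> CodonAlignment:
    """Thread CDS onto a protein alignment (PAL2NAL-style back-translation).

    Every gene's CDS must translate exactly to its ungapped protein row
    (a trailing stop codon on the CDS is ignored); protein gaps become
    ``---`` codon columns.
    """
    ids = list(protein_alignment)
    rows = []
    for gid in ids:
        prot = protein_alignment[gid].upper()
        if gid not in cds_by_gene:
            raise ValueError(f"no CDS supplied for {gid!r}")
        cds = cds_by_gene[gid].upper()
        if len(cds) % 3:
            raise ValueError(f"{gid}: CDS length {len(cds)} is not a multiple of 3")
        trans = translate_cds(cds)
        ungapped = prot.replace("-", "")
        if trans != ungapped:
            k = next(
                (i for i, (x, y) in enumerate(zip(trans, ungapped)) if x != y),
                min(len(trans), len(ungapped)),
            )
            raise ValueError(
                f"{gid}: CDS translation does not match protein row "
                f"(first mismatch at residue {k})"
            )
        codons = [cds[i : i + 3] for i in range(0, 3 * len(trans), 3)]
        out = []
        it = iter(codons)
        for aa in prot:
            out.append("---" if aa == "-" else next(it))
        rows.append("".join(out))
    return CodonAlignment(ids=ids, rows=rows)


def dnds_pair(row_a: str, row_b: str) -> NGCounts:
    """Accumulated NG86 counts for two rows of a codon alignment.

    Codon columns containing a gap or an ambiguity character in either row
    are skipped (pairwise deletion).
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    total = NGCounts()
    ok = set(_NUCS)
    for i in range(0, len(row_a), 3):
        ca, cb = row_a[i : i + 3].upper(), row_b[i : i + 3].upper()
        if set(ca) <= ok and set(cb) <= ok and ca not in STOP_CODONS and cb not in STOP_CODONS:
            total = total + ng86_counts(ca, cb)
    return total


def classify_selection(ratio: float, tol: float = 1e-9) -> str:
    """Classify a defined dN/dS ratio: positive / purifying / boundary."""
    if math.isnan(ratio):
        raise ValueError("cannot classify an undefined ratio")
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    if abs(ratio - 1.0) <= tol:
        return "boundary"
    return "positive" if ratio > 1.0 else "purifying"


@dataclass
class DnDsResult:
    """Per-family pairwise dN/dS matrix, mean and classification."""

    family: str
    pair_ratios: pd.DataFrame  # symmetric, nan where undefined
    mean_ratio: float  # nan when no pair is defined
    n_pairs: int
    n_undefined: int
    classification: Optional[str]  # None when the mean is undefined


def family_mean_dnds(alignment: CodonAlignment, family: str = "") -> DnDsResult:
    """Mean pairwise dN/dS over a family's codon alignment.

    The family mean is the arithmetic mean of the *defined* pairwise
    ratios; undefined pairs (identical rows, dS = 0, saturated) are
    excluded and counted.
    """
    n = len(alignment.ids)
    if n < 2:
        raise ValueError("family must have at least 2 members")
    mat = pd.DataFrame(np.nan, index=alignment.ids, columns=alignment.ids, dtype=float)
    defined = []
    undefined = 0
    for i in range(n):
        for j in range(i + 1, n):
            r = dnds_pair(alignment.rows[i], alignment.rows[j]).ratio
            mat.iloc[i, j] = mat.iloc[j, i] = r
            if math.isnan(r):
                undefined += 1
            else:
                defined.append(r)
    mean = float(np.mean(defined)) if defined else math.nan
    cls = None if math.isnan(mean) else classify_selection(mean)
    return DnDsResult(
        family=family,
        pair_ratios=mat,
        mean_ratio=mean,
        n_pairs=n * (n - 1) // 2,
        n_undefined=undefined,
        classification=cls,
    )
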