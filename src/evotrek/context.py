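"""Genomic-context flagging: mobile-element proximity as HGT evidence.

Genes found near insertion sequences, transposases or other mobile
elements may have entered the genome horizontally.  This module ingests
GFF3 annotations (``gene`` and ``mobile_element`` feature types) and flags
target genes whose nearest mobile element lies within a configurable
window, measured either in intervening genes or in base pairs
(edge-to-edge).  Strand is ignored: a divergently oriented neighbor is
still evidence of mobile-element association.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = ["Feature", "AnnotationSet", "ContextFlag", "flag_mobile_context", "read_gff3"]

GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


@dataclass(frozen=True)
class Feature:
    """One annotated feature; coordinates 0-based half-open internally."""

    id: str
    contig: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str
    type: str  # "gene" | "mobile_element"


def _parse_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.split(";"):
        part = part.strip()
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


class AnnotationSet:
    """Per-genome features, sorted per contig by start coordinate."""

    def __init__(self, features: Iterable[Feature]):
        self.by_contig: dict[str, list[Feature]] = {}
        self.by_id: dict[str, Feature] = {}
        for f in features:
            if f.start > f.end:
                raise ValueError(f"feature {f.id}: start > end")
            self.by_contig.setdefault(f.contig, []).append(f)
            if f.id in self.by_id:
                raise ValueError(f"duplicate feature id {f.id}")
            self.by_id[f.id] = f
        for contig in self.by_contig:
            self.by_contig[contig].sort(key=lambda f: (f.start, f.end, f.id))

    @classmethod
    def from_gff3(cls, path: str | Path) -> "AnnotationSet":
        return cls(read_gff3(path))


def read_gff3(path: str | Path) -> list[Feature]:
    """Read gene and mobile_element features from a GFF3 file.

    On-disk coordinates are 1-based inclusive; they are converted to
    0-based half-open.  Features without an ``ID`` attribute get a
    positional id.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", names=GFF_COLUMNS, header=None, dtype=str
    )
    feats = []
    for i, row in df.iterrows():
        if row["type"] not in ("gene", "mobile_element"):
            continue
        start, end = int(row["start"]), int(row["end"])
        if start < 1 or end < start:
            raise ValueError(f"{path}: invalid coordinates {start}..{end}")
        attrs = _parse_attributes(row["attributes"])
        fid = attrs.get("ID", f"{Path(path).stem}_feat{i}")
        feats.append(
            Feature(
                id=fid,
                contig=row["seqid"],
                start=start - 1,
                end=end,
                strand=row["strand"],
                type=row["type"],
            )
        )
    return feats


@dataclass
class ContextFlag:
    gene_id: str
    nearest_element: Optional[str]
    distance_genes: Optional[int]  # intervening genes between gene and element
    distance_bp: Optional[int]  # edge-to-edge; 0 when adjacent or overlapping
    flagged: bool


def _bp_distance(a: Feature, b: Feature) -> int:
    if a.end <= b.start:
        return b.start - a.end
    if b.end <= a.start:
        return a.start - b.end
    return 0  # overlapping


def flag_mobile_context(
    annotations: AnnotationSet,
    targets: Sequence[str],
    window_genes: int = 3,
    window_bp: int = 5000,
) -> list[ContextFlag]:
    """Flag target genes with a mobile element within the proximity window.

    A target is flagged when some mobile element on its contig lies within
    ``window_genes`` intervening genes OR within ``window_bp`` base pairs
    edge-to-edge.  The reported nearest element is chosen by smallest bp
    distance, ties broken by smallest id.
    """
    flags = []
    for gid in targets:
        if gid not in annotations.by_id:
            raise KeyError(f"target gene {gid!r} not annotated")
        gene = annotations.by_id[gid]
        contig_feats = annotations.by_contig[gene.contig]
        genes_sorted = [f for f in contig_feats if f.type == "gene"]
        elements = [f for f in contig_feats if f.type == "mobile_element"]
        if not elements:
            flags.append(ContextFlag(gid, None, None, None, False))
            continue
        best: Optional[tuple[int, int, str]] = None  # (bp, intervening, id)
        flagged = False
        for el in elements:
            bp = _bp_distance(gene, el)
            # genes lying strictly between the two features
            intervening = sum(
                1
                for f in genes_sorted
                if f.id != gid
                and f.start >= min(gene.end, el.end)
                and f.end <= max(gene.start, el.start)
            )
            if intervening <= window_genes or bp <= window_bp:
                flagged = True
            if best is None or (bp, el.id) < (best[0], best[2]):
                best = (bp, intervening, el.id)
        bp, intervening, el_id = best
        flags.append(ContextFlag(gid, el_id, intervening, bp, flagged))
    return flags
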