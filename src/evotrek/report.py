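"""Final event table, annotated tree and pipeline orchestration.

``run_pipeline`` wires the stages end to end: (synthetic or on-disk)
genomes -> all-vs-all protein homology search -> gene families and
presence/absence matrix -> weighted-parsimony gain/loss mapping on the
species tree -> per-family mean dN/dS -> nucleotide-identity clusters ->
mobile-element context flags -> one TSV row per family plus a Newick tree
whose branches carry the assigned events as bracketed comments.  All
outputs are deterministic for a fixed config and seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
from Bio import SeqIO

from . import __version__
from .context import AnnotationSet, ContextFlag, flag_mobile_context
from .identity import identity_clusters, pairwise_identity
from .inventory import build_matrix, cluster_families, copy_number_table, find_homologs
from .parsimony import EventMap, build_event_map, replay_events
from .phylo import parse_newick, root_with_outgroup, write_newick
from .selection import CodonAlignment, DnDsResult, family_mean_dnds
from .simulate import SimConfig, emit_dataset, simulate_dataset

__all__ = ["render_event_table", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


DEFAULT_THRESHOLDS = {
    "min_bit_like": 50.0,
    "min_coverage": 0.5,
    "cost_gain": 2.0,
    "cost_loss": 1.0,
    "window_genes": 3,
    "window_bp": 5000,
    "identity_threshold": 100.0,
}


def _fmt(x: Optional[float]) -> str:
    if x is None or (isinstance(x, float) and x != x):
        return "NA"
    return format(x, ".6g")


def render_event_table(
    event_map: EventMap,
    matrix: pd.DataFrame,
    outdir: str | Path,
    dnds: Optional[Mapping[str, DnDsResult]] = None,
    clusters: Optional[Mapping[str, list[list[str]]]] = None,
    flags: Optional[Mapping[str, list[ContextFlag]]] = None,
) -> dict[str, Path]:
    """Write the per-family event report and the event-annotated tree.

    One TSV row per family: per-taxon presence, the canonical per-branch
    events, the co-optimal scenario count, mean dN/dS with its
    classification, 100%-identity clusters and mobile-element context
    flags.  Branch events also go onto the Newick tree as bracketed
    comments.  Deterministic: identical inputs give byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = event_map.tree
    taxa = list(matrix.columns)
    dnds = dnds or {}
    clusters = clusters or {}
    flags = flags or {}

    rows = []
    branch_events: dict[int, list[str]] = {}
    for fam in matrix.index:
        fe = event_map.families[str(fam)]
        column = {t: int(matrix.loc[fam, t]) for t in taxa}
        # shared replay invariant, asserted at render time
        if replay_events(tree, fe.root_state, fe.events) != column:
            raise AssertionError(f"events for {fam} do not replay to the matrix")
        ev_str = ";".join(
            f"{tree.nodes[nid].name}:{kind}" for nid, kind in fe.events
        )
        for nid, kind in fe.events:
            branch_events.setdefault(nid, []).append(f"{fam}:{kind}")
        dd = dnds.get(str(fam))
        cl = clusters.get(str(fam))
        fl = flags.get(str(fam), [])
        n_flagged = sum(1 for f in fl if f.flagged)
        row = {"family": fam}
        row.update({t: column[t] for t in taxa})
        row.update(
            {
                "root_state": fe.root_state,
                "events": ev_str,
                "n_scenarios": fe.n_scenarios,
                "scenario_overflow": int(fe.overflow),
                "mean_dnds": _fmt(dd.mean_ratio) if dd else "NA",
                "selection": (dd.classification or "undefined") if dd else "NA",
                "undefined_pairs": dd.n_undefined if dd else "NA",
                "identity_clusters": (
                    "|".join(",".join(c) for c in cl) if cl else "NA"
                ),
                "hgt_context": int(n_flagged > 0),
                "members_flagged": n_flagged,
                "duplication": ",".join(fe.annotations.get("duplication", [])),
            }
        )
        rows.append(row)

    files: dict[str, Path] = {}
    report = pd.DataFrame(rows)
    files["report"] = p = outdir / "report.tsv"
    report.to_csv(p, sep="\t", index=False)
    comments = {
        nid: "&events=" + ",".join(sorted(evs)) for nid, evs in branch_events.items()
    }
    files["events_tree"] = p = outdir / "events.nwk"
    p.write_text(write_newick(tree, branch_comments=comments) + "\n")
    return files


# ---------------------------------------------------------------------------
# Orchestration


def _read_fasta(path: Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(config: dict, outdir: str | Path, seed: int = 0) -> dict:
    """Execute the full inference pipeline from a config mapping.

    ``config`` holds either a ``simulate`` block (SimConfig fields) or an
    ``inputs`` block (``data_dir`` with ``{taxon}.faa``,
    ``{taxon}.cds.fasta``, ``{taxon}.gff3`` plus ``tree``; optional
    ``outgroup`` to re-root), never both, plus an optional ``thresholds``
    block.  Writes the event report, identity matrices, flags, a run
    manifest, and returns the in-memory results.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if ("simulate" in config) == ("inputs" in config):
        raise PipelineError("config", "exactly one of 'simulate' or 'inputs' required")
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}

    # -- stage: data ----------------------------------------------------
    if "simulate" in config:
        cfg = SimConfig(**{**config["simulate"], "seed": seed})
        dataset = simulate_dataset(cfg)
        data_dir = outdir / "data"
        emit_dataset(dataset, data_dir)
        tree_path = data_dir / "tree.nwk"
        outgroup = None
    else:
        inputs = config["inputs"]
        data_dir = Path(inputs["data_dir"])
        tree_path = Path(inputs["tree"])
        outgroup = inputs.get("outgroup")
        dataset = None

    taxa_files = sorted(data_dir.glob("*.faa"))
    if not taxa_files:
        raise PipelineError("data", f"no protein FASTA files in {data_dir}")
    taxa = [p.name[: -len(".faa")] for p in taxa_files]

    # -- stage: inventory ----------------------------------------------
    proteins: dict[str, str] = {}
    cds: dict[str, str] = {}
    gene_taxon: dict[str, str] = {}
    for taxon in taxa:
        prot = _read_fasta(data_dir / f"{taxon}.faa")
        proteins.update(prot)
        cds.update(_read_fasta(data_dir / f"{taxon}.cds.fasta"))
        for gid in prot:
            gene_taxon[gid] = taxon
    hits = find_homologs(
        proteins,
        proteins,
        min_bit_like=thresholds["min_bit_like"],
        min_coverage=thresholds["min_coverage"],
    )
    families = cluster_families(hits, gene_taxon)
    # -- stage: tree ----------------------------------------------------
    tree = parse_newick(tree_path.read_text())
    if outgroup:
        tree = root_with_outgroup(tree, outgroup)
    matrix = build_matrix(families, tree.leaf_names())
    copy_number = copy_number_table(families, tree.leaf_names())

    # -- stage: events --------------------------------------------------
    try:
        event_map = build_event_map(
            matrix,
            tree,
            cost_gain=thresholds["cost_gain"],
            cost_loss=thresholds["cost_loss"],
            copy_number=copy_number,
        )
    except ValueError as exc:
        raise PipelineError("events", str(exc)) from exc

    # -- stage: selection + identity ------------------------------------
    fam_members = {f.family_id: [g for _, g in f.members] for f in families}
    dnds: dict[str, DnDsResult] = {}
    clusters: dict[str, list[list[str]]] = {}
    identity_dir = outdir / "identity"
    identity_dir.mkdir(exist_ok=True)
    for fid, members in fam_members.items():
        if len(members) < 2:
            continue
        seqs = {g: cds[g] for g in members if g in cds}
        if len(seqs) < 2 or len({len(s) for s in seqs.values()}) != 1:
            continue  # needs an external alignment; skipped at equal-length scale
        aln = CodonAlignment(ids=sorted(seqs), rows=[seqs[g] for g in sorted(seqs)])
        dnds[fid] = family_mean_dnds(aln, family=fid)
        ident = pairwise_identity({g: seqs[g] for g in sorted(seqs)})
        ident.to_csv(identity_dir / f"{fid}.identity.tsv", sep="\t")
        clusters[fid] = identity_clusters(ident, thresholds["identity_threshold"])

    # -- stage: context --------------------------------------------------
    flags: dict[str, list[ContextFlag]] = {}
    annots = {t: AnnotationSet.from_gff3(data_dir / f"{t}.gff3") for t in taxa}
    for fid, members in fam_members.items():
        fam_flags = []
        for g in members:
            ann = annots[gene_taxon[g]]
            if g in ann.by_id:
                fam_flags.extend(
                    flag_mobile_context(
                        ann, [g],
                        window_genes=thresholds["window_genes"],
                        window_bp=thresholds["window_bp"],
                    )
                )
        flags[fid] = fam_flags

    # -- stage: report ---------------------------------------------------
    files = render_event_table(
        event_map, matrix, outdir, dnds=dnds, clusters=clusters, flags=flags
    )
    matrix.to_csv(outdir / "matrix.tsv", sep="\t")
    copy_number.to_csv(outdir / "copy_number.tsv", sep="\t")

    manifest = {
        "package": "evotrek",
        "version": __version__,
        "seed": seed,
        "mode": "simulate" if "simulate" in config else "real",
        "thresholds": thresholds,
        "n_taxa": len(taxa),
        "n_genes": len(proteins),
        "n_families": len(families),
        "n_hits": int(len(hits)),
        "config": config,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )

    return {
        "dataset": dataset,
        "tree": tree,
        "families": families,
        "matrix": matrix,
        "copy_number": copy_number,
        "event_map": event_map,
        "dnds": dnds,
        "clusters": clusters,
        "flags": flags,
        "files": files,
        "manifest": manifest,
    }
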