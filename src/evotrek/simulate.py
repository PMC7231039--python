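"""Synthetic genus evolution simulator with a complete truth log.

Generates everything the inference stages consume — a rooted genus tree
with an outgroup, binary gene-family presence/absence evolving by gains and
losses along branches, per-family codon sequences evolving under a known
dN/dS (omega), and per-genome FASTA/GFF3 output with mobile-element
features planted next to horizontally acquired families — together with a
TruthLog recording every event, so that parsimony event mapping, selection
scans and context flagging can be validated against known ground truth.

Model summary
-------------
* Tree: Yule (pure-birth) ingroup rescaled to a configured root-to-tip
  height, plus an outgroup leaf attached at the root on a longer pendant
  branch.  All nodes carry stable names (leaves ``T01..``, internals
  ``N01..``) so the truth log can reference branches across serialization.
* Gene content: a two-state continuous-time process per family; gains fire
  on absent lineages at ``gain_rate`` per unit branch length, losses on
  present lineages at ``loss_rate``.  Dollo mode suppresses any second
  gain.  A family is flagged HGT when its presence originates from a gain
  inside the tree (root absent, >= 1 gain).
* Sequences: root codons drawn uniformly from sense codons; evolution by
  single-nucleotide proposals, accepted with probability 1 if synonymous
  and omega if nonsynonymous; proposals creating stop codons are resampled
  (they cost no time).  Branch length is the expected number of accepted
  substitutions per nucleotide site at omega = 1, so divergence is
  directly comparable to Jukes-Cantor distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .phylo import Node, SpeciesTree, parse_newick, write_newick
from .selection import CODON_TABLE, SENSE_CODONS, STOP_CODONS, translate_cds

__all__ = [
    "SimConfig",
    "TruthLog",
    "FamilyTruth",
    "SyntheticDataset",
    "simulate_species_tree",
    "simulate_genus_tree",
    "simulate_gene_content",
    "simulate_codon_sequences",
    "simulate_dataset",
    "emit_dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic genus.

    Rates are events per unit branch length (expected substitutions/site);
    ``tree_height`` is the ingroup root-to-tip height on the same scale.
    """

    n_taxa: int = 13  # total leaves including the outgroup
    n_families: int = 24
    birth_mode: str = "yule"  # or "fixed-newick"
    newick: Optional[str] = None
    gain_rate: float = 1.0
    loss_rate: float = 1.0
    root_presence_prob: float = 0.5
    dollo: bool = False
    omega_choices: tuple[float, ...] = (0.05, 1.0)  # drawn per family
    codon_length: int = 100
    tree_height: float = 0.1
    outgroup_stem_factor: float = 1.5  # outgroup pendant length / tree_height
    window_genes: int = 3
    window_bp: int = 5000
    spacer_bp: int = 100
    mobile_element_bp: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        if self.gain_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.root_presence_prob <= 1.0:
            raise ValueError("root_presence_prob must be in [0, 1]")
        if any(w < 0 for w in self.omega_choices):
            raise ValueError("omega must be >= 0")
        if self.codon_length < 1:
            raise ValueError("codon_length must be >= 1")


@dataclass
class FamilyTruth:
    family: str
    root_state: int
    events: list[tuple[str, str]]  # (child node name, "gain" | "loss")
    omega: float
    hgt: bool


@dataclass
class TruthLog:
    """Ground-truth record: per-family events plus emitted gene coordinates."""

    families: dict[str, FamilyTruth]
    gene_coords: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    # gene id -> (taxon, start, end) 1-based inclusive, filled at emission

    def replay(self, tree: SpeciesTree, family: str) -> dict[str, int]:
        """Leaf presence/absence implied by the recorded events."""
        ft = self.families[family]
        ev = {name: kind for name, kind in ft.events}
        state: dict[int, int] = {}
        out: dict[str, int] = {}
        for node in tree.preorder():
            if node.parent is None:
                s = ft.root_state
            else:
                s = state[node.parent.id]
            kind = ev.get(node.name or "")
            if kind == "gain":
                s = 1
            elif kind == "loss":
                s = 0
            state[node.id] = s
            if node.is_leaf:
                out[node.name] = s  # type: ignore[index]
        return out


# ---------------------------------------------------------------------------
# Tree simulation


def _name_nodes(tree: SpeciesTree) -> SpeciesTree:
    """Name internal nodes N01.. in preorder (leaves keep their names)."""
    k = 0
    for node in tree.preorder():
        if not node.is_leaf:
            k += 1
            node.name = f"N{k:02d}"
    return tree


def simulate_species_tree(
    n_taxa: int,
    seed: int,
    mode: str = "yule",
    newick: Optional[str] = None,
    height: float = 0.1,
) -> SpeciesTree:
    """Rooted binary tree with ``n_taxa`` uniquely named leaves.

    Yule mode grows a pure-birth tree and rescales it so the root-to-tip
    height equals ``height``; fixed-newick mode parses the supplied
    string.  Deterministic for a fixed seed.
    """
    if mode == "fixed-newick":
        if not newick:
            raise ValueError("fixed-newick mode requires a Newick string")
        return _name_nodes(parse_newick(newick))
    if mode != "yule":
        raise ValueError(f"unknown tree mode {mode!r}")
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    rng = np.random.default_rng(seed)
    counter = 0

    def new_node() -> Node:
        nonlocal counter
        node = Node(id=counter)
        counter += 1
        return node

    root = new_node()
    birth: dict[int, float] = {root.id: 0.0}
    active: list[Node] = [root]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        parent = active[i]
        parent.length = t - birth[parent.id]
        kids = [new_node(), new_node()]
        for c in kids:
            c.parent = parent
            birth[c.id] = t
        parent.children = kids
        active[i : i + 1] = kids
    t += rng.exponential(1.0 / len(active))
    for leaf in active:
        leaf.length = t - birth[leaf.id]
    # name the leaves in tree (preorder) order, then rescale to the height
    k = 0
    stack = [root]
    order: list[Node] = []
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(reversed(node.children))
    root.length = 0.0
    depth: dict[int, float] = {root.id: 0.0}
    max_depth = 0.0
    for node in order:
        if not node.children:
            k += 1
            node.name = f"T{k:02d}"
        if node.parent is not None:
            depth[node.id] = depth[node.parent.id] + node.length
            max_depth = max(max_depth, depth[node.id])
    if n_taxa > 1 and height > 0 and max_depth > 0:
        for node in order:
            node.length *= height / max_depth
    return _name_nodes(SpeciesTree(root))


def simulate_genus_tree(cfg: SimConfig, seed: int) -> SpeciesTree:
    """Ingroup Yule tree plus an outgroup leaf attached at the root.

    The outgroup pendant branch is ``outgroup_stem_factor x tree_height``
    and the ingroup stem is half the tree height, so the outgroup is
    clearly outside the radiation (the role the marine relative plays for
    an acidophilic genus).
    """
    if cfg.birth_mode == "fixed-newick":
        return simulate_species_tree(cfg.n_taxa, seed, "fixed-newick", cfg.newick)
    n_in = cfg.n_taxa - 1
    if n_in < 1:
        raise ValueError("need at least 2 taxa for an ingroup + outgroup")
    ingroup = simulate_species_tree(n_in, seed, "yule", height=cfg.tree_height)
    root = Node(id=-1)
    stem = ingroup.root
    stem.parent = root
    stem.length = 0.5 * cfg.tree_height
    out = Node(
        id=-2,
        name="OUT",
        length=cfg.outgroup_stem_factor * cfg.tree_height,
        parent=root,
    )
    root.children = [stem, out]
    # renumber ids and rename internals for a clean, stable tree
    tree = parse_newick(write_newick(SpeciesTree(root)))
    return _name_nodes(tree)


# ---------------------------------------------------------------------------
# Gene content simulation


def _evolve_state_branch(
    state: int,
    length: float,
    gain_rate: float,
    loss_rate: float,
    rng: np.random.Generator,
    gains_used: int,
    dollo: bool,
) -> tuple[int, list[str], int]:
    """Gillespie simulation of the two-state process along one branch."""
    t = 0.0
    events: list[str] = []
    while True:
        rate = gain_rate if state == 0 else loss_rate
        if dollo and state == 0 and gains_used > 0:
            rate = 0.0
        if rate <= 0.0:
            break
        t += rng.exponential(1.0 / rate)
        if t > length:
            break
        if state == 0:
            state = 1
            gains_used += 1
            events.append("gain")
        else:
            state = 0
            events.append("loss")
    return state, events, gains_used


def simulate_gene_content(
    tree: SpeciesTree,
    n_families: int,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, TruthLog]:
    """Evolve binary presence/absence for ``n_families`` along the tree.

    Returns the leaf matrix (families x taxa) and the TruthLog whose
    replay reproduces it exactly.  Multiple flips on one branch are
    collapsed to the net transition when recording events (a branch can
    carry at most one recorded event), matching what any branch-resolved
    inference could see.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    taxa = tree.leaf_names()
    rows = {}
    families: dict[str, FamilyTruth] = {}
    omegas = cfg.omega_choices
    for k in range(1, n_families + 1):
        fam = f"fam{k:04d}"
        root_state = int(rng.random() < cfg.root_presence_prob)
        omega = float(omegas[int(rng.integers(len(omegas)))])
        events: list[tuple[str, str]] = []
        state: dict[int, int] = {}
        gains_used = 0
        leaf_states: dict[str, int] = {}
        for node in tree.preorder():
            if node.parent is None:
                state[node.id] = root_state
            else:
                s0 = state[node.parent.id]
                s1, _branch_events, gains_used = _evolve_state_branch(
                    s0, node.length, cfg.gain_rate, cfg.loss_rate, rng,
                    gains_used, cfg.dollo,
                )
                if s1 != s0:  # net transition on this branch
                    events.append((node.name or "", "gain" if s1 == 1 else "loss"))
                state[node.id] = s1
            if node.is_leaf:
                leaf_states[node.name] = state[node.id]  # type: ignore[index]
        hgt = root_state == 0 and any(kind == "gain" for _, kind in events)
        families[fam] = FamilyTruth(fam, root_state, events, omega, hgt)
        rows[fam] = [leaf_states[t] for t in taxa]
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=taxa, dtype="int8")
    truth = TruthLog(families=families)
    # replay soundness, asserted per run
    for fam in families:
        assert truth.replay(tree, fam) == {
            t: int(v) for t, v in matrix.loc[fam].items()
        }, f"truth replay mismatch for {fam}"
    return matrix, truth


# ---------------------------------------------------------------------------
# Codon sequence simulation


def _evolve_codons(
    codons: list[str],
    length: float,
    omega: float,
    rng: np.random.Generator,
) -> list[str]:
    """Evolve a codon sequence along one branch (accepted-substitution scale)."""
    out = list(codons)
    n_sites = 3 * len(out)
    n_prop = rng.poisson(length * n_sites)
    for _ in range(n_prop):
        while True:  # resample stop-creating proposals: they cost no time
            site = int(rng.integers(n_sites))
            ci, pos = divmod(site, 3)
            codon = out[ci]
            cur = codon[pos]
            alt = "ACGT".replace(cur, "")[int(rng.integers(3))]
            cand = codon[:pos] + alt + codon[pos + 1 :]
            if cand not in STOP_CODONS:
                break
        if CODON_TABLE[cand] == CODON_TABLE[codon]:
            out[ci] = cand  # synonymous: always accepted
        elif rng.random() < omega:
            out[ci] = cand
    return out


def simulate_codon_sequences(
    tree: SpeciesTree,
    length_codons: int,
    omega: float,
    seed: int | np.random.Generator,
) -> dict[str, str]:
    """Evolve one family's CDS along the tree; returns leaf name -> CDS.

    The root sequence is drawn uniformly from sense codons; no emitted
    sequence contains an internal stop.
    """
    if length_codons < 1:
        raise ValueError("length_codons must be >= 1")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root_codons = [
        SENSE_CODONS[int(i)] for i in rng.integers(len(SENSE_CODONS), size=length_codons)
    ]
    seqs: dict[int, list[str]] = {}
    out: dict[str, str] = {}
    for node in tree.preorder():
        if node.parent is None:
            seqs[node.id] = root_codons
        else:
            seqs[node.id] = _evolve_codons(
                seqs[node.parent.id], node.length, omega, rng
            )
        if node.is_leaf:
            out[node.name] = "".join(seqs[node.id])  # type: ignore[index]
    return out


# ---------------------------------------------------------------------------
# Dataset assembly and emission


@dataclass
class SyntheticDataset:
    tree: SpeciesTree
    matrix: pd.DataFrame  # families x taxa
    truth: TruthLog
    sequences: dict[str, dict[str, str]]  # family -> leaf -> CDS
    cfg: SimConfig


def simulate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Full synthetic genus: tree, gene content and per-family sequences.

    One master seed spawns named substreams (tree / content / sequences)
    so each stage is independently reproducible.
    """
    ss = np.random.SeedSequence(cfg.seed)
    s_tree, s_content, s_seq = ss.spawn(3)
    tree = simulate_genus_tree(cfg, int(s_tree.generate_state(1)[0] % 2**31))
    matrix, truth = simulate_gene_content(
        tree, cfg.n_families, cfg, np.random.default_rng(s_content)
    )
    seq_rng = np.random.default_rng(s_seq)
    sequences: dict[str, dict[str, str]] = {}
    for fam in matrix.index:
        ft = truth.families[fam]
        leaf_seqs = simulate_codon_sequences(tree, cfg.codon_length, ft.omega, seq_rng)
        sequences[fam] = {
            leaf: cds for leaf, cds in leaf_seqs.items() if matrix.loc[fam, leaf] == 1
        }
    return SyntheticDataset(tree=tree, matrix=matrix, truth=truth,
                            sequences=sequences, cfg=cfg)


def gene_id(taxon: str, family: str) -> str:
    return f"{taxon}.{family}"


def emit_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write per-genome CDS/protein FASTA + GFF3, the tree and the truth TSVs.

    Genes are laid head-to-tail on one contig per genome (fixed spacers,
    forward strand); a ``mobile_element`` feature is planted in the spacer
    immediately downstream of every copy of an HGT-flagged family, within
    the configured proximity window by construction.  GFF3 coordinates are
    1-based inclusive.  Output is byte-deterministic for a fixed dataset.
    """
    ds = dataset
    cfg = ds.cfg
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    taxa = list(ds.matrix.columns)
    for fam in ds.matrix.index:
        for taxon in taxa:
            if ds.matrix.loc[fam, taxon] == 1 and taxon not in ds.sequences.get(fam, {}):
                raise ValueError(f"missing sequence for present family {fam} in {taxon}")

    for taxon in taxa:
        contig = f"{taxon}_contig1"
        fasta_cds, fasta_prot, gff = [], [], ["##gff-version 3"]
        pos = 1
        me_count = 0
        for fam in ds.matrix.index:  # stable family order
            if ds.matrix.loc[fam, taxon] != 1:
                continue
            cds = ds.sequences[fam][taxon]
            gid = gene_id(taxon, fam)
            start, end = pos, pos + len(cds) - 1
            ds.truth.gene_coords[gid] = (taxon, start, end)
            gff.append(
                f"{contig}\tevotrek_sim\tgene\t{start}\t{end}\t.\t+\t.\t"
                f"ID={gid};family={fam}"
            )
            fasta_cds.append(f">{gid}\n{cds}")
            fasta_prot.append(f">{gid}\n{translate_cds(cds)}")
            pos = end + 1 + cfg.spacer_bp
            if ds.truth.families[fam].hgt:
                me_count += 1
                me_start = end + 1 + cfg.spacer_bp // 2
                me_end = me_start + cfg.mobile_element_bp - 1
                gff.append(
                    f"{contig}\tevotrek_sim\tmobile_element\t{me_start}\t{me_end}"
                    f"\t.\t+\t.\tID={taxon}.ME{me_count:03d};near={gid}"
                )
                pos = me_end + 1 + cfg.spacer_bp
        files[f"{taxon}.cds"] = p = outdir / f"{taxon}.cds.fasta"
        p.write_text("\n".join(fasta_cds) + "\n" if fasta_cds else "")
        files[f"{taxon}.faa"] = p = outdir / f"{taxon}.faa"
        p.write_text("\n".join(fasta_prot) + "\n" if fasta_prot else "")
        files[f"{taxon}.gff3"] = p = outdir / f"{taxon}.gff3"
        p.write_text("\n".join(gff) + "\n")

    files["tree"] = p = outdir / "tree.nwk"
    p.write_text(write_newick(ds.tree) + "\n")

    rows = []
    for fam, ft in ds.truth.families.items():
        rows.append(
            {
                "family": fam,
                "root_state": ft.root_state,
                "omega": ft.omega,
                "hgt": int(ft.hgt),
                "events": ";".join(f"{n}:{k}" for n, k in ft.events),
            }
        )
    files["truth_families"] = p = outdir / "truth_families.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    files["truth_matrix"] = p = outdir / "truth_matrix.tsv"
    ds.matrix.to_csv(p, sep="\t")
    return files
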