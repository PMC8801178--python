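"""Synthetic trait-labeled trees and codon alignments with known truth.

The generator evolves codon sequences along a labeled tree under the
M0 model and can *inject* convergence: designated sites where chosen
reference branches independently substitute to the same derived amino
acid.  Injected sites are frozen (background rate zero) by default so
ground truth is unambiguous; a noisy mode keeps background evolution on
for stress tests.  Every output is reproducible bit-for-bit from the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ancestral import CodonModelM0, TreeIndex
from .genetics import CODON_TO_AA, SENSE_CODONS, SENSE_INDEX, codons_for_aa
from .io_phylo import Replacement, TraitLabeledTree, _Node
from .reference_branches import ReferenceBranch, find_reference_branches


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Injection:
    """A convergent replacement planted at one site on several branches."""

    site: int  # 1-based protein position
    target_aa: str
    branch_ids: tuple[str, ...]
    ancestral_aa: str | None = None

    def target_codon(self) -> str:
        codons = codons_for_aa(self.target_aa)
        if not codons:
            raise SimulationConfigError(f"no codon encodes {self.target_aa!r}")
        return codons[0]

    def ancestral_codon(self) -> str:
        if self.ancestral_aa is not None:
            codons = codons_for_aa(self.ancestral_aa)
            if not codons:
                raise SimulationConfigError(
                    f"no codon encodes {self.ancestral_aa!r}"
                )
            return codons[0]
        for codon in SENSE_CODONS:
            if CODON_TO_AA[codon] != self.target_aa:
                return codon
        raise AssertionError("unreachable")


@dataclass
class SimulationConfig:
    tree: TraitLabeledTree  # trait-labeled, with branch lengths
    model: CodonModelM0 = field(default_factory=CodonModelM0)
    n_codons: int = 300
    injections: tuple[Injection, ...] = ()
    forced_splits: tuple[frozenset, ...] = ()
    noisy_injections: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        sites = [inj.site for inj in self.injections]
        if len(set(sites)) != len(sites):
            raise SimulationConfigError("injection sites must be distinct")
        for inj in self.injections:
            if not (1 <= inj.site <= self.n_codons):
                raise SimulationConfigError(
                    f"injection site {inj.site} outside 1..{self.n_codons}"
                )


@dataclass
class SimulatedDataset:
    alignment: "object"  # codon MultipleSequenceAlignment of the tips
    tree: TraitLabeledTree
    traits: dict[str, str]
    node_states: dict[str, str]  # codon sequence at every node
    truth: list[Replacement]  # true per-reference-branch replacements
    branches: list[ReferenceBranch]
    config: SimulationConfig


def random_labeled_tree(
    n_c4_clades: int,
    n_c3_clades: int,
    tips_per_clade: int,
    seed: int,
    mean_backbone_length: float = 0.02,
    mean_tip_length: float = 0.01,
) -> TraitLabeledTree:
    """Yule-backbone tree of monochromatic clades plus two basal outgroups.

    Each clade is a pectinate block of ``tips_per_clade`` tips whose
    subtending edge is the intended reference branch; clade types are
    interleaved deterministically under the seed.
    """
    if n_c4_clades < 1 or n_c3_clades < 1 or tips_per_clade < 1:
        raise SimulationConfigError("clade and tip counts must be >= 1")
    rng = np.random.default_rng(seed)
    n_clades = n_c4_clades + n_c3_clades

    nodes: dict[str, _Node] = {}
    serial = [0]

    def new_id(prefix: str) -> str:
        serial[0] += 1
        return f"{prefix}{serial[0]}"

    def add(nid: str, parent: str | None, length: float | None) -> str:
        nodes[nid] = _Node(nid, parent, [], length)
        if parent is not None:
            nodes[parent].children.append(nid)
        return nid

    def elen(mean: float) -> float:
        return float(rng.exponential(mean)) + 1e-4

    # Yule backbone: split a random pending leaf until n_clades slots exist
    root = add(new_id("i"), None, None)
    ingroup = add(new_id("i"), root, elen(mean_backbone_length))
    slots = [ingroup]
    while len(slots) < n_clades:
        k = int(rng.integers(len(slots)))
        slot = slots.pop(k)
        for _ in range(2):
            slots.append(add(new_id("i"), slot, elen(mean_backbone_length)))

    # Assign clade types so that no backbone subtree is monochromatic,
    # otherwise same-type clades would merge into one reference branch.
    # Deterministic rejection sampling under the seed; for extreme type
    # ratios a perfect assignment may not exist, in which case the best
    # attempt (most reference branches) is kept.
    types = _assign_clade_types(nodes, slots, n_c4_clades, n_c3_clades, rng)
    traits: dict[str, str] = {}
    for c, (slot, ctype) in enumerate(zip(slots, types), start=1):
        tip_names = [f"{ctype.lower()}c{c:02d}_t{k+1}" for k in range(tips_per_clade)]
        # pectinate block under the slot; the slot's own edge is the
        # intended reference branch
        attach = slot
        for k, name in enumerate(tip_names):
            add(name, attach, elen(mean_tip_length))
            if k < len(tip_names) - 2:
                attach = add(new_id("i"), attach, elen(mean_tip_length))
        for name in tip_names:
            traits[name] = ctype

    for og in ("outgroup_1", "outgroup_2"):
        add(og, root, elen(mean_backbone_length * 2))
        traits[og] = "outgroup"

    # collapse the unary ingroup stem if only one clade slot was split
    return TraitLabeledTree(nodes, root, traits).prune_to(traits)


def _assign_clade_types(nodes: Mapping[str, _Node], slots: Sequence[str],
                        n_c4: int, n_c3: int, rng: np.random.Generator
                        ) -> list[str]:
    """Type labels per slot such that every multi-slot subtree is mixed."""

    def subtree_slots(nid: str) -> list[str]:
        node = nodes[nid]
        if not node.children:
            return [nid] if nid in set(slots) else []
        out = []
        for c in node.children:
            out.extend(subtree_slots(c))
        return out

    root = next(n for n in nodes.values() if n.parent is None).node_id
    groups = [
        subtree_slots(nid)
        for nid in nodes
        if nodes[nid].children and len(subtree_slots(nid)) >= 2
    ]
    slot_pos = {s: i for i, s in enumerate(slots)}

    best: list[str] | None = None
    best_score = -1
    for _ in range(200):
        types = ["C4"] * n_c4 + ["C3"] * n_c3
        rng.shuffle(types)
        mono = sum(
            1 for g in groups
            if len({types[slot_pos[s]] for s in g}) == 1
        )
        if mono == 0:
            return types
        if -mono > best_score:
            best_score = -mono
            best = types
    assert best is not None
    return best


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Evolve codon sequences and return tips plus full ground truth."""
    from .io_phylo import MultipleSequenceAlignment

    rng = np.random.default_rng(config.seed)
    tree = config.tree
    traits = dict(tree.traits)
    branches = find_reference_branches(tree, traits, config.forced_splits)
    by_id = {b.branch_id: b for b in branches}
    for inj in config.injections:
        unknown = set(inj.branch_ids) - set(by_id)
        if unknown:
            raise SimulationConfigError(
                f"injection branches are not reference branches: {sorted(unknown)}"
            )

    tidx = TreeIndex(tree)
    lengths = tidx.require_lengths()
    P = config.model.transition_matrices(lengths)
    cum = np.cumsum(P, axis=2)
    n_sites = config.n_codons
    pi = config.model.codon_frequencies

    injected_cols = {inj.site - 1: inj for inj in config.injections}
    # node index of the child end of each injected branch
    inj_child: dict[int, set[int]] = {}
    for col, inj in injected_cols.items():
        children = set()
        for bid in inj.branch_ids:
            b = by_id[bid]
            children.add(tidx.index[tree.mrca(b.tip_set)]
                         if len(b.tip_set) > 1
                         else tidx.index[next(iter(b.tip_set))])
        inj_child[col] = children

    states = np.empty((tidx.n_nodes, n_sites), dtype=int)
    root_states = rng.choice(len(SENSE_CODONS), size=n_sites, p=pi)
    for col, inj in injected_cols.items():
        root_states[col] = SENSE_INDEX[inj.ancestral_codon()]
    states[tidx.root] = root_states

    frozen = np.zeros(n_sites, dtype=bool)
    if not config.noisy_injections:
        frozen[list(injected_cols)] = True

    for v in reversed(range(tidx.n_nodes)):  # preorder
        if v == tidx.root:
            continue
        parent_states = states[tidx.parent[v]]
        u = rng.random(n_sites)
        drawn = (u[:, None] > cum[v][parent_states]).sum(axis=1)
        drawn = np.minimum(drawn, len(SENSE_CODONS) - 1)
        child = np.where(frozen, parent_states, drawn)
        for col, children in inj_child.items():
            if v in children:
                child[col] = SENSE_INDEX[injected_cols[col].target_codon()]
        states[v] = child

    codon_arr = np.array(SENSE_CODONS)
    node_states = {
        tidx.ids[v]: "".join(codon_arr[states[v]]) for v in range(tidx.n_nodes)
    }
    records = tuple(
        (tip, node_states[tip]) for tip in sorted(tree.tip_labels)
    )
    alignment = MultipleSequenceAlignment(
        gene_id="sim", records=records, molecule="codon"
    )

    truth = _true_replacements(tree, tidx, states, branches)
    return SimulatedDataset(
        alignment=alignment,
        tree=tree,
        traits=traits,
        node_states=node_states,
        truth=truth,
        branches=branches,
        config=config,
    )


def _true_replacements(tree: TraitLabeledTree, tidx: TreeIndex,
                       states: np.ndarray,
                       branches: Sequence[ReferenceBranch]) -> list[Replacement]:
    out: list[Replacement] = []
    for b in branches:
        child = (tree.mrca(b.tip_set) if len(b.tip_set) > 1
                 else next(iter(b.tip_set)))
        parent = tree.parent(child)
        ci, pi_ = tidx.index[child], tidx.index[parent]
        for s in range(states.shape[1]):
            anc = CODON_TO_AA[SENSE_CODONS[states[pi_, s]]]
            der = CODON_TO_AA[SENSE_CODONS[states[ci, s]]]
            if anc != der:
                out.append(
                    Replacement(
                        gene_id="sim", site=s + 1, branch_id=b.branch_id,
                        ancestral_aa=anc, derived_aa=der,
                    )
                )
    return out
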