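"""Reference-branch identification and branch-pair enumeration.

A *reference branch* subtends the most recent common ancestor of a
maximal clade whose sampled tips all share one photosynthesis type; it
is the unit on which amino-acid replacements are called.  Sister clades
of the same type that are known from denser external sampling to be
independent origins can be kept apart with *forced splits* — tip sets
declared in configuration, never inferred from the sampled tree.
"""

from __future__ import annotations

import itertools
import logging
import string
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_phylo import TraitError, TraitLabeledTree, TreeError

log = logging.getLogger(__name__)

CATEGORIES = ("C4:C4", "C3:C4", "C3:C3")


@dataclass(frozen=True)
class ReferenceBranch:
    branch_id: str
    child_node: str
    type: str  # "C3" | "C4"
    tip_set: frozenset[str]
    forced: bool = False
    branch_length: float | None = None

    @property
    def n_tips(self) -> int:
        return len(self.tip_set)


@dataclass(frozen=True)
class BranchPair:
    branch_a: str
    branch_b: str
    category: str
    length_sum: float | None = None

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.branch_a, self.branch_b))


def _category(type_a: str, type_b: str) -> str:
    if type_a == type_b:
        return f"{type_a}:{type_b}"
    return "C3:C4"


def _branch_labels(n: int) -> list[str]:
    letters = string.ascii_uppercase
    labels = list(letters)
    for a in letters:
        for b in letters:
            labels.append(a + b)
    return labels[:n]


def find_reference_branches(
    tree: TraitLabeledTree,
    traits: Mapping[str, str] | None = None,
    forced_splits: Sequence[Iterable[str]] = (),
) -> list[ReferenceBranch]:
    """Find every maximal single-type clade, honouring forced splits.

    Singleton tips qualify (a terminal branch is a valid reference
    branch).  Outgroup tips never contribute.  Branch ids are uppercase
    letters assigned in a deterministic depth-first traversal whose
    child order is the tree's canonical (smallest-descendant-tip) order,
    so they are invariant to tip order in the source newick.
    """
    traits = dict(traits if traits is not None else tree.traits)
    tips = set(tree.tip_labels)
    unlabeled = tips - set(traits)
    if unlabeled:
        raise TraitError(f"ingroup tips without trait labels: {sorted(unlabeled)}")
    ingroup = {t for t in tips if traits[t] in ("C3", "C4")}
    if not ingroup:
        raise TraitError("no C3/C4-labeled tips in tree")

    forced_sets = [frozenset(fs) for fs in forced_splits]
    for fs in forced_sets:
        if not fs <= ingroup:
            raise TraitError(f"forced split has non-ingroup tips: {sorted(fs - ingroup)}")
        if tree.tip_set(tree.mrca(fs)) & ingroup != fs:
            raise TreeError(f"forced split is not a clade: {sorted(fs)}")

    def clade_type(node_id: str) -> str | None:
        types = {traits[t] for t in tree.tip_set(node_id)}
        return types.pop() if types in ({"C3"}, {"C4"}) else None

    found: list[tuple[str, str, bool]] = []  # (node_id, type, forced)

    def emit_within(node_id: str) -> None:
        """Emit branches inside a maximal clade partitioned by forced splits."""
        tipset = tree.tip_set(node_id)
        if tipset in forced_sets:
            found.append((node_id, clade_type(node_id), True))
            return
        if any(fs < tipset for fs in forced_sets):
            for child in tree.children(node_id):
                emit_within(child)
            return
        found.append((node_id, clade_type(node_id), False))

    def descend(node_id: str) -> None:
        ctype = clade_type(node_id)
        if ctype is not None:
            if node_id == tree.root_id:
                log.warning("entire tree is monochromatic (%s); using root clade", ctype)
            if any(fs < tree.tip_set(node_id) for fs in forced_sets):
                emit_within(node_id)
            else:
                forced = tree.tip_set(node_id) in forced_sets
                found.append((node_id, ctype, forced))
            return
        for child in tree.children(node_id):
            descend(child)

    descend(tree.root_id)

    # order of discovery is already canonical depth-first tip order
    labels = _branch_labels(len(found))
    branches = []
    for label, (node_id, ctype, forced) in zip(labels, found):
        branches.append(
            ReferenceBranch(
                branch_id=label,
                child_node=node_id,
                type=ctype,
                tip_set=tree.tip_set(node_id),
                forced=forced,
                branch_length=tree.branch_length(node_id),
            )
        )
    return branches


def enumerate_pairs(branches: Sequence[ReferenceBranch]) -> list[BranchPair]:
    """All unordered pairs of reference branches, with their category."""
    if len(branches) < 2:
        raise ValueError("need at least two reference branches to form pairs")
    pairs = []
    for a, b in itertools.combinations(branches, 2):
        length_sum = None
        if a.branch_length is not None and b.branch_length is not None:
            length_sum = a.branch_length + b.branch_length
        pairs.append(
            BranchPair(
                branch_a=a.branch_id,
                branch_b=b.branch_id,
                category=_category(a.type, b.type),
                length_sum=length_sum,
            )
        )
    return pairs


def pair_length_sums(pairs: Sequence[BranchPair]) -> dict[str, list[float]]:
    """Per-category vectors of pair branch-length sums (length-bias control)."""
    out: dict[str, list[float]] = {cat: [] for cat in CATEGORIES}
    for p in pairs:
        if p.length_sum is None:
            raise ValueError(
                f"pair {sorted(p.pair)} lacks branch lengths (cladogram input)"
            )
        out[p.category].append(p.length_sum)
    return out


def branch_report_frame(branches: Sequence[ReferenceBranch]):
    import pandas as pd

    return pd.DataFrame(
        {
            "branch_id": [b.branch_id for b in branches],
            "type": [b.type for b in branches],
            "n_tips": [b.n_tips for b in branches],
            "tips": [";".join(sorted(b.tip_set)) for b in branches],
            "forced": [b.forced for b in branches],
            "branch_length": [b.branch_length for b in branches],
        }
    )
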