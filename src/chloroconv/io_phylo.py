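"""Input/output for every external format the pipeline touches.

FASTA codon/protein alignments (via Biopython), rooted newick trees with
optional branch lengths and internal support labels (via DendroPy),
TSV trait tables mapping species to photosynthesis type, and TSV
replacement tables (one amino-acid change along one reference branch at
one site).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as _dc_replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO

from .genetics import AMINO_ACIDS, GAP

log = logging.getLogger(__name__)

TRAIT_TOKENS = ("C3", "C4", "outgroup")

_DNA_ALPHABET = frozenset("ACGT" + GAP)
_PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + GAP)


class AlignmentError(ValueError):
    """Ragged rows, bad alphabet, or broken reading frame."""


class TreeError(ValueError):
    """Unparseable or structurally invalid newick input."""


class TraitError(ValueError):
    """Unknown photosynthesis-type token or missing label."""


class ReplacementTableError(ValueError):
    """Replacement row violating its invariants."""


# ---------------------------------------------------------------------------
# Alignments


@dataclass(frozen=True)
class MultipleSequenceAlignment:
    """An in-frame codon or protein alignment for one gene."""

    gene_id: str
    records: tuple[tuple[str, str], ...]
    molecule: str  # "codon" | "protein"

    def __post_init__(self) -> None:
        if self.molecule not in ("codon", "protein"):
            raise ValueError(f"unknown molecule {self.molecule!r}")
        if not self.records:
            raise AlignmentError(f"{self.gene_id}: empty alignment")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"{self.gene_id}: ragged sequence lengths {sorted(lengths)}")
        names = [name for name, _ in self.records]
        if len(set(names)) != len(names):
            raise AlignmentError(f"{self.gene_id}: duplicate species ids")
        alphabet = _DNA_ALPHABET if self.molecule == "codon" else _PROTEIN_ALPHABET
        for name, seq in self.records:
            bad = set(seq) - alphabet
            if bad:
                raise AlignmentError(
                    f"{self.gene_id}/{name}: illegal characters {sorted(bad)}"
                )
        if self.molecule == "codon" and self.length % 3 != 0:
            raise AlignmentError(
                f"{self.gene_id}: codon alignment length {self.length} not divisible by 3"
            )

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.records)

    def sequence(self, species: str) -> str:
        for name, seq in self.records:
            if name == species:
                return seq
        raise KeyError(species)

    def subset(self, species: Iterable[str]) -> "MultipleSequenceAlignment":
        wanted = set(species)
        kept = tuple((n, s) for n, s in self.records if n in wanted)
        return _dc_replace(self, records=kept)

    def column(self, i: int) -> str:
        return "".join(seq[i] for _, seq in self.records)


def read_fasta_alignment(path: str | Path, molecule: str, gene_id: str | None = None
                         ) -> MultipleSequenceAlignment:
    """Read a FASTA alignment, uppercasing and validating invariants."""
    path = Path(path)
    records = tuple(
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    )
    return MultipleSequenceAlignment(
        gene_id=gene_id or path.stem, records=records, molecule=molecule
    )


def write_fasta_alignment(msa: MultipleSequenceAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in msa.records:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Trees


@dataclass
class _Node:
    node_id: str
    parent: str | None
    children: list[str]
    length: float | None = None
    support: str | None = None


class TraitLabeledTree:
    """Rooted phylogeny whose tips may carry photosynthesis-type labels.

    Internal node ids are derived deterministically: children are ordered
    by their lexicographically smallest descendant tip, and internal
    nodes are numbered N1, N2, ... in preorder under that canonical
    ordering, so ids are invariant to tip order in the source newick.
    """

    def __init__(self, nodes: dict[str, _Node], root_id: str,
                 traits: Mapping[str, str] | None = None):
        self._nodes = nodes
        self.root_id = root_id
        self.traits: dict[str, str] = dict(traits or {})
        self._tipsets: dict[str, frozenset[str]] = {}
        self._canonicalize()

    # -- construction -------------------------------------------------

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree,
                      traits: Mapping[str, str] | None = None) -> "TraitLabeledTree":
        nodes: dict[str, _Node] = {}
        counter = [0]

        def build(dnode, parent_id):
            if dnode.is_leaf():
                if dnode.taxon is None or not dnode.taxon.label:
                    raise TreeError("unlabeled tip")
                nid = dnode.taxon.label
            else:
                counter[0] += 1
                nid = f"@{counter[0]}"  # provisional; renamed in _canonicalize
            if nid in nodes:
                raise TreeError(f"duplicate tip name {nid!r}")
            nodes[nid] = _Node(
                node_id=nid,
                parent=parent_id,
                children=[],
                length=dnode.edge.length,
                support=(dnode.label if not dnode.is_leaf() else None),
            )
            if parent_id is not None:
                nodes[parent_id].children.append(nid)
            for child in dnode.child_nodes():
                build(child, nid)
            return nid

        root_id = build(dtree.seed_node, None)
        return cls(nodes, root_id, traits)

    def _canonicalize(self) -> None:
        # compute tip sets bottom-up, order children by smallest tip,
        # rename internal nodes in canonical preorder
        order = self._postorder_raw()
        mintip: dict[str, str] = {}
        for nid in order:
            node = self._nodes[nid]
            if not node.children:
                self._tipsets[nid] = frozenset([nid])
                mintip[nid] = nid
            else:
                node.children.sort(key=lambda c: mintip[c])
                self._tipsets[nid] = frozenset().union(
                    *(self._tipsets[c] for c in node.children)
                )
                mintip[nid] = min(mintip[c] for c in node.children)
        renames: dict[str, str] = {}
        k = 0
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            node = self._nodes[nid]
            if node.children:
                k += 1
                renames[nid] = f"N{k}"
            stack.extend(reversed(node.children))
        new_nodes: dict[str, _Node] = {}
        for nid, node in self._nodes.items():
            new_id = renames.get(nid, nid)
            node.node_id = new_id
            node.parent = renames.get(node.parent, node.parent)
            node.children = [renames.get(c, c) for c in node.children]
            new_nodes[new_id] = node
        self._nodes = new_nodes
        self._tipsets = {renames.get(n, n): s for n, s in self._tipsets.items()}
        self.root_id = renames.get(self.root_id, self.root_id)

    def _postorder_raw(self) -> list[str]:
        out: list[str] = []
        stack: list[tuple[str, bool]] = [(self.root_id, False)]
        while stack:
            nid, done = stack.pop()
            if done:
                out.append(nid)
            else:
                stack.append((nid, True))
                for c in self._nodes[nid].children:
                    stack.append((c, False))
        return out

    # -- queries ------------------------------------------------------

    def node(self, node_id: str) -> _Node:
        return self._nodes[node_id]

    @property
    def node_ids(self) -> tuple[str, ...]:
        return tuple(self._nodes)

    def postorder(self) -> list[str]:
        return self._postorder_raw()

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(sorted(self._tipsets[self.root_id]))

    def is_tip(self, node_id: str) -> bool:
        return not self._nodes[node_id].children

    def parent(self, node_id: str) -> str | None:
        return self._nodes[node_id].parent

    def children(self, node_id: str) -> tuple[str, ...]:
        return tuple(self._nodes[node_id].children)

    def branch_length(self, node_id: str) -> float | None:
        return self._nodes[node_id].length

    @property
    def has_lengths(self) -> bool:
        return all(
            self._nodes[n].length is not None
            for n in self._nodes if n != self.root_id
        )

    def tip_set(self, node_id: str) -> frozenset[str]:
        return self._tipsets[node_id]

    def mrca(self, tips: Iterable[str]) -> str:
        wanted = frozenset(tips)
        missing = wanted - self._tipsets[self.root_id]
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")
        best = self.root_id
        changed = True
        while changed:
            changed = False
            for child in self._nodes[best].children:
                if wanted <= self._tipsets[child]:
                    best = child
                    changed = True
                    break
        return best

    def prune_to(self, species: Iterable[str]) -> "TraitLabeledTree":
        """Restrict to the given tips, suppressing unifurcations.

        Suppressed edges have their lengths summed; the result keeps the
        same trait map restricted to surviving tips.
        """
        keep = set(species) & set(self._tipsets[self.root_id])
        if len(keep) < 2:
            raise TreeError("pruning would leave fewer than two tips")

        def rebuild(nid):
            node = self._nodes[nid]
            if not node.children:
                if nid in keep:
                    return (nid, node.length, None, [])
                return None
            subs = [rebuild(c) for c in node.children]
            subs = [s for s in subs if s is not None]
            if not subs:
                return None
            if len(subs) == 1:
                cid, clen, csup, cch = subs[0]
                total = None
                if node.length is not None or clen is not None:
                    total = (node.length or 0.0) + (clen or 0.0)
                return (cid, total, csup, cch)
            return (nid, node.length, node.support, subs)

        built = rebuild(self.root_id)
        assert built is not None
        nodes: dict[str, _Node] = {}

        def materialize(entry, parent_id):
            nid, length, support, childsubs = entry
            nodes[nid] = _Node(nid, parent_id, [], length, support)
            if parent_id is not None:
                nodes[parent_id].children.append(nid)
            for sub in childsubs:
                materialize(sub, nid)

        materialize(built, None)
        nodes[built[0]].length = None  # root carries no branch
        traits = {s: t for s, t in self.traits.items() if s in keep}
        return TraitLabeledTree(nodes, built[0], traits)

    def with_traits(self, traits: Mapping[str, str]) -> "TraitLabeledTree":
        tree = self.copy()
        tree.traits = dict(traits)
        return tree

    def copy(self) -> "TraitLabeledTree":
        nodes = {
            nid: _Node(n.node_id, n.parent, list(n.children), n.length, n.support)
            for nid, n in self._nodes.items()
        }
        return TraitLabeledTree(nodes, self.root_id, dict(self.traits))

    # -- serialization ------------------------------------------------

    def to_newick(self) -> str:
        def fmt(nid):
            node = self._nodes[nid]
            if not node.children:
                body = _quote_label(nid)
            else:
                inner = ",".join(fmt(c) for c in node.children)
                body = f"({inner})" + (_quote_label(node.support) if node.support else "")
            if node.length is not None and node.parent is not None:
                body += f":{node.length:.10g}"
            return body

        return fmt(self.root_id) + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def _quote_label(label: str) -> str:
    if any(ch in label for ch in "(),:;[] \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_newick(path: str | Path) -> TraitLabeledTree:
    """Read a single rooted newick tree; lengths and support optional."""
    text = Path(path).read_text()
    return parse_newick(text)


def parse_newick(text: str) -> TraitLabeledTree:
    if text.count("(") != text.count(")"):
        raise TreeError("unbalanced parentheses in newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise TreeError(f"newick parse failure: {exc}") from exc
    return TraitLabeledTree.from_dendropy(dtree)


# ---------------------------------------------------------------------------
# Trait tables


def normalize_trait(token: str) -> str:
    t = token.strip().lower()
    for canon in TRAIT_TOKENS:
        if t == canon.lower():
            return canon
    raise TraitError(f"unknown photosynthesis type {token!r}")


def read_trait_table(path: str | Path) -> dict[str, str]:
    """Read a TSV with columns species_id, type (case-insensitive tokens)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return {}
    if df.empty and df.columns.size == 0:
        return {}
    required = {"species_id", "type"}
    if not required <= set(df.columns):
        raise TraitError(f"trait table must have columns {sorted(required)}")
    traits = {
        str(row.species_id): normalize_trait(str(row.type))
        for row in df.itertuples()
    }
    counts = trait_counts(traits)
    log.info("trait table: %s", counts)
    return traits


def write_trait_table(traits: Mapping[str, str], path: str | Path) -> None:
    df = pd.DataFrame(
        {"species_id": list(traits), "type": [traits[s] for s in traits]}
    )
    df.to_csv(path, sep="\t", index=False)


def trait_counts(traits: Mapping[str, str]) -> dict[str, int]:
    counts = {t: 0 for t in TRAIT_TOKENS}
    for t in traits.values():
        counts[t] += 1
    # the study's own tally folded outgroups into the C3 column
    counts["C3_including_outgroup"] = counts["C3"] + counts["outgroup"]
    return counts


def reconcile_traits(tree: TraitLabeledTree, traits: Mapping[str, str]
                     ) -> TraitLabeledTree:
    """Attach traits to a tree, dropping species present on one side only.

    Mismatches are logged as warnings rather than raised: per-gene
    species sets legitimately differ from the master tree.
    """
    tips = set(tree.tip_labels)
    labeled = set(traits)
    only_tree = tips - labeled
    only_table = labeled - tips
    if only_tree:
        log.warning("tips without trait labels dropped: %s", sorted(only_tree))
    if only_table:
        log.warning("trait rows absent from tree ignored: %s", sorted(only_table))
    shared = tips & labeled
    if only_tree:
        tree = tree.prune_to(shared)
    return tree.with_traits({s: normalize_trait(traits[s]) for s in shared})


# ---------------------------------------------------------------------------
# Replacement tables


@dataclass(frozen=True)
class Replacement:
    """One amino-acid change along one reference branch at one site.

    ``site`` is the 1-based reference-species protein coordinate where
    available, else an alignment-column fallback id of the form "col:<n>".
    """

    gene_id: str
    site: int | str
    branch_id: str
    ancestral_aa: str
    derived_aa: str
    posterior_min: float | None = None

    def __post_init__(self) -> None:
        if self.ancestral_aa == self.derived_aa:
            raise ReplacementTableError(
                f"{self.gene_id}:{self.site}:{self.branch_id}: "
                "ancestral and derived states identical"
            )

    @property
    def key(self) -> tuple[str, int | str]:
        return (self.gene_id, self.site)


REPLACEMENT_COLUMNS = ("gene", "site", "branch", "ancestral", "derived")


def _parse_site(token: str) -> int | str:
    token = str(token)
    return int(token) if token.isdigit() else token


def write_replacement_table(rows: Sequence[Replacement], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(REPLACEMENT_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                f"{r.gene_id}\t{r.site}\t{r.branch_id}\t{r.ancestral_aa}\t{r.derived_aa}\n"
            )


def read_replacement_table(path: str | Path) -> list[Replacement]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if tuple(df.columns) != REPLACEMENT_COLUMNS:
        raise ReplacementTableError(
            f"expected columns {REPLACEMENT_COLUMNS}, found {tuple(df.columns)}"
        )
    return [
        Replacement(
            gene_id=row.gene,
            site=_parse_site(row.site),
            branch_id=row.branch,
            ancestral_aa=row.ancestral,
            derived_aa=row.derived,
        )
        for row in df.itertuples()
    ]
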