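"""Packaged synthetic study fixture.

A stand-in for the grass-chloroplast study dataset, generated in code
(text formats only, no external downloads): a 64-tip trait-labeled tree
(43 C4 + 19 C3 PACMAD-style ingroup tips in 22 monochromatic clades,
plus two outgroups) and a Supplemental-Information-3-style replacement
table over the resulting 13 C4 / 9 C3 reference branches.

The replacement table is SYNTHETIC: the real per-site study data are
not redistributed here.  It is constructed so that the classification
pipeline reproduces the study's headline counts exactly —

* 217 distinct convergent sites (104 C4:C4 / 120 C3:C4 / 34 C3:C3),
* 201 distinct non-convergent sites (96 / 121 / 39),
* twelve C4-specific conserved convergent sites in 7 genes,
* seven C4 branches sharing NdhH H18Q (plus one C3 branch),
* exactly two true-convergent sites (MatK 205, NdhF 636),

while every other property (which genes, which branch pairs carry the
remaining events) is an arbitrary deterministic arrangement.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np

from .io_phylo import Replacement, TraitLabeledTree, _Node

# Letter layout along the ladder, with forced sister pairs (B,C), (E,F),
# (J,K), (S,T); 13 C4 and 9 C3 reference branches.
CLADE_ORDER = tuple("ABCDEFGHIJKLMNOPQRSTUV")
C4_BRANCHES = tuple("ABCEFGIJKPSTV")
C3_BRANCHES = tuple("DHLMNOQRU")
FORCED_PAIRS = (("B", "C"), ("E", "F"), ("J", "K"), ("S", "T"))

_CLADE_SIZES = {
    "A": 5, "B": 3, "C": 3, "D": 3, "E": 4, "F": 3, "G": 4, "H": 2,
    "I": 3, "J": 3, "K": 3, "L": 2, "M": 2, "N": 2, "O": 2, "P": 3,
    "Q": 2, "R": 2, "S": 3, "T": 3, "U": 2, "V": 3,
}


def clade_tips(letter: str) -> tuple[str, ...]:
    return tuple(f"sp{letter}{k:02d}" for k in range(1, _CLADE_SIZES[letter] + 1))


def study_forced_splits() -> tuple[frozenset, ...]:
    out = []
    for a, b in FORCED_PAIRS:
        out.append(frozenset(clade_tips(a)))
        out.append(frozenset(clade_tips(b)))
    return tuple(out)


def study_traits() -> dict[str, str]:
    traits = {}
    for letter in CLADE_ORDER:
        ctype = "C4" if letter in C4_BRANCHES else "C3"
        for tip in clade_tips(letter):
            traits[tip] = ctype
    traits["outgroup_1"] = "outgroup"
    traits["outgroup_2"] = "outgroup"
    return traits


def _reference_lengths() -> dict[str, float]:
    """Evenly spaced reference-branch lengths, matched between types.

    The study conditions include *no* length difference between the
    photosynthesis-type categories (Mann-Whitney P > 0.5 on pair sums),
    so both types span the same range.
    """
    lengths = {}
    for letters in (C4_BRANCHES, C3_BRANCHES):
        for letter, ln in zip(letters, np.linspace(0.004, 0.028, len(letters))):
            lengths[letter] = float(ln)
    return lengths


def study_tree() -> TraitLabeledTree:
    """The 64-tip trait-labeled ladder tree with branch lengths."""
    nodes: dict[str, _Node] = {}
    serial = itertools.count(1)

    def add(nid, parent, length):
        nodes[nid] = _Node(nid, parent, [], length)
        if parent is not None:
            nodes[parent].children.append(nid)
        return nid

    ref_len = _reference_lengths()

    def build_clade(letter: str, parent: str) -> None:
        stem = add(f"clade_{letter}", parent, ref_len[letter])
        tips = clade_tips(letter)
        attach = stem
        for k, tip in enumerate(tips):
            add(tip, attach, 0.005)
            if k < len(tips) - 2:
                attach = add(f"c{letter}{next(serial)}", attach, 0.005)

    units: list[object] = []
    paired = {a for p in FORCED_PAIRS for a in p}
    i = 0
    while i < len(CLADE_ORDER):
        letter = CLADE_ORDER[i]
        if letter in paired:
            units.append((letter, CLADE_ORDER[i + 1]))
            i += 2
        else:
            units.append(letter)
            i += 1

    root = add("root", None, None)
    spine = add("ingroup", root, 0.01)
    for j, unit in enumerate(units):
        last = j == len(units) - 1
        if isinstance(unit, tuple):
            pair_node = add(f"pair_{unit[0]}{unit[1]}", spine, 0.01)
            for letter in unit:
                build_clade(letter, pair_node)
        else:
            build_clade(unit, spine)
        if not last:
            if j < len(units) - 2:
                spine = add(f"spine{j}", spine, 0.01)
    add("outgroup_1", root, 0.05)
    add("outgroup_2", root, 0.05)

    return TraitLabeledTree(nodes, "root", study_traits())


# ---------------------------------------------------------------------------
# Synthetic replacement table


_FILLER_GENES = (
    "atpA", "atpB", "atpE", "atpF", "atpH", "atpI", "ndhA", "ndhB", "ndhC",
    "ndhD", "ndhE", "ndhJ", "ndhK", "petA", "petB", "petD", "petG", "petN",
    "psaA", "psaB", "psaC", "psaI", "psaJ", "psbA", "psbB", "psbC", "psbD",
    "psbE", "psbH", "psbI", "rpl2", "rpl14", "rpl16", "rpl20", "rpl22",
    "rps2", "rps4", "rps7", "rps8", "rps11",
)


def _special_replacements() -> list[Replacement]:
    rows: list[Replacement] = []

    def site(gene, pos, anc, branch_to_derived):
        for branch, der in branch_to_derived:
            rows.append(Replacement(gene, pos, branch, anc, der))

    def shared(gene, pos, anc, der, branches):
        site(gene, pos, anc, [(b, der) for b in branches])

    # seven C4 branches plus one C3 branch share NdhH H18Q; the C3 copy
    # keeps the site off the C4-specific list
    shared("ndhH", 18, "H", "Q", ["A", "B", "C", "E", "F", "G", "I", "D"])

    # twelve C4-specific conserved convergent sites in seven genes
    shared("rbcL", 101, "V", "I", ["G", "I", "J", "A", "B", "C"])
    shared("rbcL", 309, "M", "I", ["E", "F", "G", "I", "J"])
    shared("rbcL", 328, "A", "S", ["P", "S", "T", "V"])
    shared("rbcL", 143, "T", "A", ["A", "E", "V"])
    shared("rbcL", 281, "A", "S", ["B", "K", "P"])
    shared("ndhI", 25, "S", "G", ["C", "E", "G", "J", "S", "V"])
    shared("ndhI", 44, "A", "T", ["F", "I", "T"])
    shared("matK", 204, "L", "F", ["A", "G", "P", "V"])
    shared("ndhF", 250, "I", "V", ["B", "J", "S"])
    shared("ndhG", 120, "A", "S", ["C", "K", "T"])
    shared("rpoC1", 300, "T", "I", ["E", "I", "P"])
    shared("rpoC2", 500, "S", "N", ["F", "J", "V"])

    # the two true-convergent sites (different ancestral states)
    site("matK", 205, "T", [("G", "S")])
    site("matK", 205, "K", [("I", "S")])
    site("ndhF", 636, "L", [("V", "I")])
    shared("ndhF", 636, "K", "I", ["N", "R", "U"])

    # C3-specific convergent sites
    shared("ndhF", 557, "L", "F", ["N", "R", "U"])
    shared("ndhF", 700, "A", "S", ["D", "H", "Q"])
    shared("rpoC2", 875, "H", "Y", ["L", "M", "O"])

    # one site convergent independently in C4:C4 and C3:C3 (different
    # derived states between the types, hence non-convergent across)
    shared("rps3", 100, "A", "S", ["P", "V"])
    shared("rps3", 100, "A", "T", ["N", "R"])
    return rows


def _filler_replacements() -> list[Replacement]:
    c4_pairs = list(itertools.combinations(C4_BRANCHES, 2))
    c3_pairs = list(itertools.combinations(C3_BRANCHES, 2))
    mixed = [(a, b) for a in C4_BRANCHES for b in C3_BRANCHES]

    # (count, branch-set generator, derived pattern) per filler block;
    # "con" gives every branch the same derived state, "nc" all different
    blocks = [
        (69, lambda i: c4_pairs[(i * 7) % 78], "con"),
        (20, lambda i: c4_pairs[(i * 11) % 78] + (C3_BRANCHES[i % 9],), "con"),
        (80, lambda i: mixed[(i * 5) % 117], "con"),
        (18, lambda i: (C4_BRANCHES[i % 13],) + c3_pairs[(i * 5) % 36], "con"),
        (11, lambda i: c3_pairs[(i * 3) % 36], "con"),
        (66, lambda i: c4_pairs[(i * 13) % 78], "nc"),
        (30, lambda i: c4_pairs[(i * 17) % 78] + (C3_BRANCHES[(i + 4) % 9],), "nc"),
        (65, lambda i: mixed[(i * 7) % 117], "nc"),
        (25, lambda i: (C4_BRANCHES[(i + 5) % 13],) + c3_pairs[(i * 7) % 36], "nc"),
        (14, lambda i: c3_pairs[(i * 5) % 36], "nc"),
    ]
    derived_nc = ("V", "L", "I")
    rows: list[Replacement] = []
    serial = 0
    for count, pick, kind in blocks:
        for i in range(count):
            gene = _FILLER_GENES[serial % len(_FILLER_GENES)]
            pos = 10 + 10 * (serial // len(_FILLER_GENES))
            for k, branch in enumerate(pick(i)):
                der = "S" if kind == "con" else derived_nc[k]
                rows.append(Replacement(gene, pos, branch, "A", der))
            serial += 1
    return rows


def study_replacements() -> list[Replacement]:
    """The full synthetic Supp-3-style replacement table."""
    return _special_replacements() + _filler_replacements()


def write_study_fixture(directory) -> dict[str, str]:
    """Write tree, traits, forced splits and replacement table as text."""
    from pathlib import Path

    from .io_phylo import write_replacement_table, write_trait_table

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tree = study_tree()
    paths = {
        "tree": str(directory / "tree.nwk"),
        "traits": str(directory / "traits.tsv"),
        "replacements": str(directory / "replacements.tsv"),
        "forced_splits": str(directory / "forced_splits.txt"),
    }
    tree.write_newick(paths["tree"])
    write_trait_table(study_traits(), paths["traits"])
    write_replacement_table(study_replacements(), paths["replacements"])
    with open(paths["forced_splits"], "w") as fh:
        for split in study_forced_splits():
            fh.write(",".join(sorted(split)) + "\n")
    return paths
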