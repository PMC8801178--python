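"""Pairwise classification of replacements and category summaries.

Two replacements at the same site on two different reference branches
form one *pair event*:

* convergent — same derived amino acid; split into *parallel*
  (identical ancestral states, the dominant case) and *true convergent*
  (different ancestral states);
* non-convergent — different derived amino acids, regardless of the
  ancestral states.

Events aggregate three ways, mirroring how such studies report them:
per distinct site, per gene, and per pair of reference branches, within
each photosynthesis-type category (C4:C4, C3:C4, C3:C3).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_phylo import Replacement
from .reference_branches import CATEGORIES, BranchPair, ReferenceBranch

CONVERGENT_PARALLEL = "convergent_parallel"
CONVERGENT_TRUE = "convergent_true"
NON_CONVERGENT = "non_convergent"

PAIR_ROWS = ("no_replacements", "no_con", "with_con", "with_nc",
             "con_gt_nc", "con_gt_1")


@dataclass(frozen=True)
class PairEvent:
    gene_id: str
    site: int | str
    pair: BranchPair
    event_class: str
    ancestral_a: str
    derived_a: str
    ancestral_b: str
    derived_b: str

    @property
    def is_convergent(self) -> bool:
        return self.event_class in (CONVERGENT_PARALLEL, CONVERGENT_TRUE)

    @property
    def site_key(self) -> tuple[str, int | str]:
        return (self.gene_id, self.site)


def classify_site_pair(repl_a: Replacement, repl_b: Replacement,
                       pair: BranchPair) -> PairEvent:
    """Classify the joint outcome of two replacements at one site."""
    if repl_a.key != repl_b.key:
        raise ValueError("replacements are not at the same (gene, site)")
    if repl_a.branch_id == repl_b.branch_id:
        raise ValueError("cannot pair a branch with itself")
    if repl_a.derived_aa != repl_b.derived_aa:
        cls = NON_CONVERGENT
    elif repl_a.ancestral_aa == repl_b.ancestral_aa:
        cls = CONVERGENT_PARALLEL
    else:
        cls = CONVERGENT_TRUE
    return PairEvent(
        gene_id=repl_a.gene_id,
        site=repl_a.site,
        pair=pair,
        event_class=cls,
        ancestral_a=repl_a.ancestral_aa,
        derived_a=repl_a.derived_aa,
        ancestral_b=repl_b.ancestral_aa,
        derived_b=repl_b.derived_aa,
    )


def compare_all_pairs(replacements: Sequence[Replacement],
                      pairs: Sequence[BranchPair]) -> list[PairEvent]:
    """One PairEvent per (pair, gene, site) where both members replaced."""
    by_site: dict[tuple[str, int | str], dict[str, Replacement]] = defaultdict(dict)
    for r in replacements:
        by_site[r.key][r.branch_id] = r
    events: list[PairEvent] = []
    for key, branch_map in by_site.items():
        for pair in pairs:
            ra = branch_map.get(pair.branch_a)
            rb = branch_map.get(pair.branch_b)
            if ra is not None and rb is not None:
                events.append(classify_site_pair(ra, rb, pair))
    return events


@dataclass
class CategorySummary:
    """Aggregated convergence counts per photosynthesis-type category."""

    n_events: dict[str, dict[str, int]]  # category -> class -> count
    con_sites: dict[str, set]
    nc_sites: dict[str, set]
    con_genes: dict[str, set]
    nc_genes: dict[str, set]
    per_pair: dict[frozenset, dict[str, int]]  # pair -> {"con": n, "nc": n}
    pair_category: dict[frozenset, str]
    events: list[PairEvent] = field(default_factory=list)

    # -- site / gene counts -------------------------------------------

    def n_con_sites(self, category: str) -> int:
        return len(self.con_sites[category])

    def n_nc_sites(self, category: str) -> int:
        return len(self.nc_sites[category])

    def n_con_sites_total(self) -> int:
        return len(set().union(*self.con_sites.values()))

    def n_nc_sites_total(self) -> int:
        return len(set().union(*self.nc_sites.values()))

    def unique_sites(self, category: str, convergent: bool,
                     by_any_event: bool = False) -> set:
        """Sites counted only in this category.

        ``by_any_event=False`` restricts by events of the same class
        (a convergent-unique site has convergent events nowhere else);
        ``True`` requires the site to have no event of any kind in any
        other category.
        """
        own = self.con_sites if convergent else self.nc_sites
        sites = set(own[category])
        for other in CATEGORIES:
            if other == category:
                continue
            sites -= own[other]
            if by_any_event:
                sites -= self.con_sites[other]
                sites -= self.nc_sites[other]
        return sites

    def unique_genes(self, category: str, convergent: bool,
                     by_any_event: bool = False) -> set:
        own = self.con_genes if convergent else self.nc_genes
        genes = set(own[category])
        for other in CATEGORIES:
            if other == category:
                continue
            genes -= own[other]
            if by_any_event:
                genes -= self.con_genes[other]
                genes -= self.nc_genes[other]
        return genes

    # -- event counts -------------------------------------------------

    def n_con_events(self, category: str) -> int:
        ev = self.n_events[category]
        return ev[CONVERGENT_PARALLEL] + ev[CONVERGENT_TRUE]

    def n_nc_events(self, category: str) -> int:
        return self.n_events[category][NON_CONVERGENT]

    # -- pair-level rows ----------------------------------------------

    def pair_row_count(self, row: str, category: str) -> int:
        if row not in PAIR_ROWS:
            raise ValueError(f"unknown pair row {row!r}; valid: {PAIR_ROWS}")
        n = 0
        for pair, cat in self.pair_category.items():
            if cat != category:
                continue
            counts = self.per_pair[pair]
            con, nc = counts["con"], counts["nc"]
            ok = {
                "no_replacements": con == 0 and nc == 0,
                "no_con": con == 0,
                "with_con": con > 0,
                "with_nc": nc > 0,
                "con_gt_nc": con > nc,
                "con_gt_1": con > 1,
            }[row]
            n += ok
        return n

    def n_pairs(self, category: str) -> int:
        return sum(1 for c in self.pair_category.values() if c == category)


def summarize(events: Sequence[PairEvent],
              pairs: Sequence[BranchPair]) -> CategorySummary:
    """Aggregate pair events into site, gene and pair-level counts."""
    n_events = {c: {CONVERGENT_PARALLEL: 0, CONVERGENT_TRUE: 0, NON_CONVERGENT: 0}
                for c in CATEGORIES}
    con_sites: dict[str, set] = {c: set() for c in CATEGORIES}
    nc_sites: dict[str, set] = {c: set() for c in CATEGORIES}
    con_genes: dict[str, set] = {c: set() for c in CATEGORIES}
    nc_genes: dict[str, set] = {c: set() for c in CATEGORIES}
    per_pair = {p.pair: {"con": 0, "nc": 0} for p in pairs}
    pair_category = {p.pair: p.category for p in pairs}
    for e in events:
        cat = e.pair.category
        n_events[cat][e.event_class] += 1
        if e.is_convergent:
            con_sites[cat].add(e.site_key)
            con_genes[cat].add(e.gene_id)
            per_pair[e.pair.pair]["con"] += 1
        else:
            nc_sites[cat].add(e.site_key)
            nc_genes[cat].add(e.gene_id)
            per_pair[e.pair.pair]["nc"] += 1
    return CategorySummary(
        n_events=n_events,
        con_sites=con_sites,
        nc_sites=nc_sites,
        con_genes=con_genes,
        nc_genes=nc_genes,
        per_pair=per_pair,
        pair_category=pair_category,
        events=list(events),
    )


def true_convergent_sites(events: Sequence[PairEvent]) -> set:
    """Sites with at least one convergent event whose ancestors differ."""
    return {e.site_key for e in events if e.event_class == CONVERGENT_TRUE}


def type_specific_convergent_sites(
    events: Sequence[PairEvent],
    branch_types: Mapping[str, str],
    photo_type: str = "C4",
    min_branches: int = 3,
) -> list[tuple[str, int | str]]:
    """Convergent sites private to one photosynthesis type.

    A site qualifies when at least ``min_branches`` reference branches
    of ``photo_type`` share the same derived amino acid there and the
    site is otherwise conserved: every replaced branch at the site is
    one of those convergent same-type branches (no replacement of any
    kind elsewhere).
    """
    if min_branches < 2:
        raise ValueError("min_branches must be >= 2")
    per_site: dict[tuple, list[PairEvent]] = defaultdict(list)
    for e in events:
        per_site[e.site_key].append(e)
    hits = []
    for key, evs in per_site.items():
        branches: set[str] = set()
        derived: set[str] = set()
        convergent_only = True
        for e in evs:
            branches.update((e.pair.branch_a, e.pair.branch_b))
            derived.update((e.derived_a, e.derived_b))
            if not e.is_convergent:
                convergent_only = False
        if not convergent_only or len(derived) != 1:
            continue
        if len(branches) < min_branches:
            continue
        if any(branch_types[b] != photo_type for b in branches):
            continue
        hits.append(key)
    return sorted(hits, key=lambda k: (k[0], str(k[1])))


# ---------------------------------------------------------------------------
# Report frames


def table1_frame(summary: CategorySummary) -> pd.DataFrame:
    """Site/gene counts with unique rows, shaped like the study's Table 1."""
    rows = {}
    for label, fn_con, fn_nc in (
        ("Sites", summary.n_con_sites, summary.n_nc_sites),
        ("Sites*", lambda c: len(summary.unique_sites(c, True)),
         lambda c: len(summary.unique_sites(c, False))),
        ("Genes", lambda c: len(summary.con_genes[c]),
         lambda c: len(summary.nc_genes[c])),
        ("Genes*", lambda c: len(summary.unique_genes(c, True)),
         lambda c: len(summary.unique_genes(c, False))),
    ):
        row = {}
        for cat in CATEGORIES:
            con, nc = fn_con(cat), fn_nc(cat)
            row[f"{cat} Con"] = con
            row[f"{cat} NC"] = nc
            row[f"{cat} Ratio"] = round(con / nc, 2) if nc else float("nan")
        rows[label] = row
    return pd.DataFrame(rows).T


def table2_frame(summary: CategorySummary) -> pd.DataFrame:
    """Pair-level rows (counts and proportions), like the study's Table 2."""
    data = {}
    for cat in CATEGORIES:
        total = summary.n_pairs(cat)
        col = {}
        for row in PAIR_ROWS:
            n = summary.pair_row_count(row, cat)
            col[row] = n
            col[row + "_prop"] = round(n / total, 2) if total else float("nan")
        data[cat] = col
    return pd.DataFrame(data)


def events_frame(events: Sequence[PairEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [e.gene_id for e in events],
            "site": [e.site for e in events],
            "branch_a": [e.pair.branch_a for e in events],
            "branch_b": [e.pair.branch_b for e in events],
            "category": [e.pair.category for e in events],
            "class": [e.event_class for e in events],
            "ancestral_a": [e.ancestral_a for e in events],
            "derived_a": [e.derived_a for e in events],
            "ancestral_b": [e.ancestral_b for e in events],
            "derived_b": [e.derived_b for e in events],
        }
    )


def site_matrix(replacements: Sequence[Replacement],
                branches: Sequence[ReferenceBranch]) -> pd.DataFrame:
    """Wide site-by-branch matrix of 'A>D' states (Figure-3 style)."""
    keys = sorted({r.key for r in replacements}, key=lambda k: (k[0], str(k[1])))
    by = {(r.gene_id, r.site, r.branch_id): r for r in replacements}
    data = {}
    for b in branches:
        data[b.branch_id] = [
            (lambda r: f"{r.ancestral_aa}>{r.derived_aa}" if r else "")(
                by.get((g, s, b.branch_id))
            )
            for (g, s) in keys
        ]
    frame = pd.DataFrame(data, index=pd.MultiIndex.from_tuples(keys,
                                                               names=["gene", "site"]))
    return frame
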