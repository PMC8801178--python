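"""Calling amino-acid replacements along reference branches.

Each reference branch's reconstructed sequence is compared with its
parent node's sequence; a differing site is one replacement.  Only
reference branches are scanned — changes inside the subtended clades
are deliberately ignored, which makes the downstream convergence counts
conservative.
"""

from __future__ import annotations

import logging
from typing import Sequence

from .ancestral import AncestralStates, SiteMap
from .genetics import AMINO_ACIDS, GAP
from .io_phylo import Replacement
from .reference_branches import ReferenceBranch

log = logging.getLogger(__name__)


def call_branch_replacements(
    anc_states: AncestralStates,
    ref_branch: ReferenceBranch,
    site_map: SiteMap | None = None,
    gene_id: str = "",
    min_posterior: float = 0.0,
) -> list[Replacement]:
    """Replacements along one reference branch.

    A site yields a replacement when the parent and child best states
    are both unambiguous amino acids, differ, and both node posteriors
    reach ``min_posterior``.  Sites where the reference species has a
    gap are reported under an alignment-column fallback id and still
    count.
    """
    tree = anc_states.tree
    present = ref_branch.tip_set & set(tree.tip_labels)
    if not present:
        raise KeyError(
            f"branch {ref_branch.branch_id}: no tips present in reconstruction"
        )
    if len(present) == 1:
        child = next(iter(present))
    else:
        child = tree.mrca(present)
    parent = tree.parent(child)
    if parent is None:
        raise KeyError(
            f"branch {ref_branch.branch_id}: child node is the root; "
            "no ancestral branch to compare against"
        )
    if child not in anc_states.best or parent not in anc_states.best:
        raise KeyError(
            f"branch {ref_branch.branch_id}: nodes missing from reconstruction"
        )

    out: list[Replacement] = []
    aa_set = set(AMINO_ACIDS)
    for k in range(anc_states.n_sites):
        pa = anc_states.best[parent][k]
        ch = anc_states.best[child][k]
        if pa == ch or pa not in aa_set or ch not in aa_set:
            continue
        if anc_states.ambiguous[parent][k] or anc_states.ambiguous[child][k]:
            continue
        p_min = min(anc_states.posterior[parent][k], anc_states.posterior[child][k])
        if p_min < min_posterior:
            continue
        site = site_map.label(k) if site_map is not None else k + 1
        out.append(
            Replacement(
                gene_id=gene_id,
                site=site,
                branch_id=ref_branch.branch_id,
                ancestral_aa=pa,
                derived_aa=ch,
                posterior_min=float(p_min),
            )
        )
    return out


def call_all_replacements(
    anc_states: AncestralStates,
    branches: Sequence[ReferenceBranch],
    site_map: SiteMap | None = None,
    gene_id: str = "",
    min_posterior: float = 0.0,
) -> list[Replacement]:
    """Replacements over every reference branch with data for this gene."""
    out: list[Replacement] = []
    for branch in branches:
        if not branch.tip_set & set(anc_states.tree.tip_labels):
            log.warning(
                "%s: branch %s has no sequenced tips; skipped",
                gene_id, branch.branch_id,
            )
            continue
        out.extend(
            call_branch_replacements(
                anc_states, branch, site_map, gene_id, min_posterior
            )
        )
    return out
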