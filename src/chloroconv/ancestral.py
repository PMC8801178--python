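"""Ancestral protein-sequence reconstruction.

Two reconstruction paths are provided:

* **Fitch parsimony** on the translated alignment — fast, model-free,
  used as an independent check and as the default for large simulation
  batteries.  Ambiguous nodes are flagged and excluded from replacement
  calling.
* **Marginal maximum likelihood** under the basic codon substitution
  model (M0: one transition/transversion ratio kappa, one
  nonsynonymous/synonymous ratio omega, equilibrium codon frequencies;
  no site classes).  Likelihoods come from Felsenstein pruning with
  per-site scaling; node posteriors from the inside-outside (up/down)
  recursion; codon posteriors are collapsed to amino acids by summation
  before the argmax, since replacements are defined on amino acids.

The pruning and marginal machinery is written over an arbitrary finite
state space so tiny-state fixtures can be checked against brute-force
enumeration; the codon model supplies 61-state matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from . import genetics
from .genetics import (
    AMINO_ACIDS,
    GAP,
    N_SENSE,
    SENSE_CODONS,
    SENSE_INDEX,
    aa_collapse_matrix,
    codon_pair_structure,
    translate_codon,
)
from .io_phylo import AlignmentError, MultipleSequenceAlignment, TraitLabeledTree

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Translation and site filtering


def translate_codons(msa: MultipleSequenceAlignment) -> MultipleSequenceAlignment:
    """Translate an in-frame codon alignment to protein.

    '---' becomes the gap residue; internal stops and partially gapped
    codons are errors (stop codons are expected to have been stripped
    upstream).
    """
    if msa.molecule != "codon":
        raise ValueError("translate_codons expects a codon alignment")
    out = []
    for name, seq in msa.records:
        residues = []
        for i in range(0, len(seq), 3):
            codon = seq[i: i + 3]
            try:
                residues.append(translate_codon(codon))
            except ValueError as exc:
                raise AlignmentError(
                    f"{msa.gene_id}/{name} codon {i // 3 + 1}: {exc}"
                ) from exc
        out.append((name, "".join(residues)))
    return MultipleSequenceAlignment(
        gene_id=msa.gene_id, records=tuple(out), molecule="protein"
    )


@dataclass(frozen=True)
class SiteMap:
    """Provenance of filtered protein sites.

    Maps filtered-site index -> original alignment column (0-based) and,
    where the reference species has a residue there, its 1-based
    protein coordinate.  Sites falling in a reference-species gap keep
    an alignment-column fallback label "col:<n>" (1-based column).
    """

    ref_species: str | None
    columns: tuple[int, ...]
    ref_coords: tuple[int | None, ...]

    def __len__(self) -> int:
        return len(self.columns)

    def label(self, filtered_index: int) -> int | str:
        coord = self.ref_coords[filtered_index]
        if coord is not None:
            return coord
        if self.ref_species is None:
            # no reference configured: plain 1-based alignment columns
            return self.columns[filtered_index] + 1
        return f"col:{self.columns[filtered_index] + 1}"


def filter_gap_sites(
    protein_msa: MultipleSequenceAlignment,
    ingroup_species: Sequence[str],
    ref_species: str | None = None,
    all_species: bool = False,
) -> tuple[MultipleSequenceAlignment, SiteMap]:
    """Drop columns with a gap in any ingroup species.

    The exclusion rule covers ingroup species only by default (outgroup
    gaps are tolerated); ``all_species=True`` extends it to every row.
    """
    ingroup = [s for s in ingroup_species if s in protein_msa.species]
    scan = protein_msa.species if all_species else tuple(ingroup)
    seqs = {name: seq for name, seq in protein_msa.records}
    keep = [
        col
        for col in range(protein_msa.length)
        if all(seqs[s][col] != GAP for s in scan)
    ]
    if not keep:
        log.warning("%s: no columns survive gap filtering", protein_msa.gene_id)
    ref_coords: list[int | None] = []
    if ref_species is not None and ref_species in seqs:
        ref_seq = seqs[ref_species]
        running = np.cumsum([c != GAP for c in ref_seq])
        for col in keep:
            ref_coords.append(int(running[col]) if ref_seq[col] != GAP else None)
    else:
        ref_coords = [None] * len(keep)
    records = tuple(
        (name, "".join(seq[c] for c in keep)) for name, seq in protein_msa.records
    )
    filtered = MultipleSequenceAlignment(
        gene_id=protein_msa.gene_id, records=records, molecule="protein"
    )
    return filtered, SiteMap(ref_species, tuple(keep), tuple(ref_coords))


# ---------------------------------------------------------------------------
# Tree indexing


class TreeIndex:
    """Array view of a TraitLabeledTree in postorder (root last)."""

    def __init__(self, tree: TraitLabeledTree):
        self.tree = tree
        self.ids: list[str] = tree.postorder()
        self.index = {nid: i for i, nid in enumerate(self.ids)}
        n = len(self.ids)
        self.parent = np.full(n, -1, dtype=int)
        self.children: list[list[int]] = [[] for _ in range(n)]
        self.lengths = np.full(n, np.nan)
        self.is_tip = np.zeros(n, dtype=bool)
        for i, nid in enumerate(self.ids):
            p = tree.parent(nid)
            if p is not None:
                self.parent[i] = self.index[p]
                self.children[self.index[p]].append(i)
            bl = tree.branch_length(nid)
            if bl is not None:
                self.lengths[i] = bl
            self.is_tip[i] = tree.is_tip(nid)
        self.root = self.index[tree.root_id]

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    def require_lengths(self) -> np.ndarray:
        nonroot = np.arange(self.n_nodes) != self.root
        if np.isnan(self.lengths[nonroot]).any():
            raise ValueError("tree has missing branch lengths (cladogram input)")
        return self.lengths


# ---------------------------------------------------------------------------
# Generic pruning over an arbitrary state space


def _up_partials(tidx: TreeIndex, P: np.ndarray, tip_partials: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Felsenstein pruning with per-site log scaling.

    P: (n_nodes, k, k) transition matrices for the edge above each node
    (ignored for the root).  tip_partials: (n_nodes, n_sites, k) with
    rows filled for tips.  Returns (partials, logscale) where
    partials[v, s] * exp(logscale[v, s]) is the true partial likelihood.
    """
    n_nodes, n_sites, k = tip_partials.shape
    partials = np.array(tip_partials, dtype=float)
    logscale = np.zeros((n_nodes, n_sites))
    for v in range(n_nodes):
        if tidx.is_tip[v]:
            continue
        acc = np.ones((n_sites, k))
        scale = np.zeros(n_sites)
        for c in tidx.children[v]:
            acc = acc * (partials[c] @ P[c].T)
            scale += logscale[c]
            mx = acc.max(axis=1)
            mx[mx == 0.0] = 1.0
            acc /= mx[:, None]
            scale += np.log(mx)
        partials[v] = acc
        logscale[v] = scale
    return partials, logscale


def generic_log_likelihood(tidx: TreeIndex, P: np.ndarray,
                           tip_partials: np.ndarray, root_freqs: np.ndarray,
                           site_weights: np.ndarray | None = None) -> float:
    partials, logscale = _up_partials(tidx, P, tip_partials)
    site_l = partials[tidx.root] @ root_freqs
    logs = np.log(site_l) + logscale[tidx.root]
    if site_weights is None:
        return float(logs.sum())
    return float(logs @ site_weights)


def generic_marginal_posteriors(tidx: TreeIndex, P: np.ndarray,
                                tip_partials: np.ndarray,
                                root_freqs: np.ndarray) -> np.ndarray:
    """Marginal posterior state distribution at every node and site.

    Up partials then a preorder flow-down pass; returns
    (n_nodes, n_sites, k), each row normalized to 1.
    """
    n_nodes, n_sites, k = tip_partials.shape
    partials, _ = _up_partials(tidx, P, tip_partials)
    down = np.zeros_like(partials)
    down[tidx.root] = root_freqs[None, :]
    # preorder = reversed postorder
    for v in reversed(range(n_nodes)):
        if tidx.is_tip[v] and v != tidx.root:
            continue
        kids = tidx.children[v]
        up_msgs = {c: partials[c] @ P[c].T for c in kids}
        for c in kids:
            m = down[v].copy()
            for w in kids:
                if w != c:
                    m *= up_msgs[w]
            flow = m @ P[c]
            norm = flow.sum(axis=1, keepdims=True)
            norm[norm == 0.0] = 1.0
            down[c] = flow / norm
    post = down * partials
    norm = post.sum(axis=2, keepdims=True)
    norm[norm == 0.0] = 1.0
    return post / norm


# ---------------------------------------------------------------------------
# The M0 codon model


@dataclass
class CodonModelM0:
    """Basic codon substitution model (one omega, one kappa, no site classes).

    The rate matrix has q_ij = pi_j * {1, kappa} * {1, omega} for single
    nucleotide changes (transversion/transition, synonymous/
    nonsynonymous) and 0 otherwise, scaled so the expected substitution
    rate at equilibrium is 1: branch lengths are expected substitutions
    per codon.
    """

    kappa: float = 2.0
    omega: float = 0.2
    codon_frequencies: np.ndarray = field(
        default_factory=lambda: np.full(N_SENSE, 1.0 / N_SENSE)
    )
    genetic_code: str = "table11"

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.omega <= 0:
            raise ValueError("kappa and omega must be positive")
        f = np.asarray(self.codon_frequencies, dtype=float)
        if f.shape != (N_SENSE,) or (f < 0).any():
            raise ValueError("codon_frequencies must be a nonnegative 61-vector")
        f = np.maximum(f, 1e-10)
        self.codon_frequencies = f / f.sum()

    def rate_matrix(self) -> np.ndarray:
        single, transition, synonymous = codon_pair_structure()
        q = np.zeros((N_SENSE, N_SENSE))
        q[single] = 1.0
        q[single & transition] *= self.kappa
        q[single & ~synonymous] *= self.omega
        q *= self.codon_frequencies[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        rate = -float(self.codon_frequencies @ np.diag(q))
        return q / rate

    def _eigen(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        pi = self.codon_frequencies
        sq = np.sqrt(pi)
        q = self.rate_matrix()
        sym = sq[:, None] * q / sq[None, :]
        lam, u = np.linalg.eigh(0.5 * (sym + sym.T))
        left = u.T * sq[None, :]       # U^T D^{1/2}
        right = u / sq[:, None]        # D^{-1/2} U
        return lam, right, left

    def transition_matrices(self, lengths: np.ndarray) -> np.ndarray:
        """P(t) for each branch length; shape (len(lengths), 61, 61)."""
        lam, right, left = self._eigen()
        t = np.nan_to_num(np.asarray(lengths, dtype=float), nan=0.0)
        expd = np.exp(np.clip(t[:, None] * lam[None, :], -700, 700))
        p = np.einsum("ik,bk,kj->bij", right, expd, left)
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=2, keepdims=True)
        return p


def f3x4_frequencies(msa: MultipleSequenceAlignment) -> np.ndarray:
    """Empirical codon frequencies from position-specific nucleotide counts."""
    counts = np.zeros((3, 4))
    nt_index = {nt: i for i, nt in enumerate(genetics.NUCLEOTIDES)}
    for _, seq in msa.records:
        for i in range(0, len(seq), 3):
            codon = seq[i: i + 3]
            if GAP in codon:
                continue
            for pos, nt in enumerate(codon):
                counts[pos, nt_index[nt]] += 1
    counts = np.maximum(counts, 1e-6)
    freqs = counts / counts.sum(axis=1, keepdims=True)
    f = np.array(
        [
            freqs[0, nt_index[c[0]]] * freqs[1, nt_index[c[1]]] * freqs[2, nt_index[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return f / f.sum()


def f61_frequencies(msa: MultipleSequenceAlignment, pseudocount: float = 0.1
                    ) -> np.ndarray:
    counts = np.full(N_SENSE, pseudocount)
    for _, seq in msa.records:
        for i in range(0, len(seq), 3):
            idx = SENSE_INDEX.get(seq[i: i + 3])
            if idx is not None:
                counts[idx] += 1
    return counts / counts.sum()


def _codon_tip_partials(msa: MultipleSequenceAlignment, tidx: TreeIndex
                        ) -> np.ndarray:
    """Indicator partials for tips; gap codons are missing data (all ones)."""
    n_sites = msa.length // 3
    partials = np.zeros((tidx.n_nodes, n_sites, N_SENSE))
    seqs = {name: seq for name, seq in msa.records}
    for v in range(tidx.n_nodes):
        if not tidx.is_tip[v]:
            continue
        seq = seqs[tidx.ids[v]]
        for s in range(n_sites):
            codon = seq[3 * s: 3 * s + 3]
            if GAP in codon:
                partials[v, s, :] = 1.0
            else:
                idx = SENSE_INDEX.get(codon)
                if idx is None:
                    raise AlignmentError(
                        f"{msa.gene_id}/{tidx.ids[v]}: stop or invalid codon {codon!r}"
                    )
                partials[v, s, idx] = 1.0
    return partials


def log_likelihood(codon_msa: MultipleSequenceAlignment, tree: TraitLabeledTree,
                   model: CodonModelM0) -> float:
    """Total log-likelihood of the alignment under M0 on the given tree."""
    tidx = TreeIndex(tree.prune_to(set(codon_msa.species) & set(tree.tip_labels)))
    lengths = tidx.require_lengths()
    sub = codon_msa.subset(tidx.tree.tip_labels)
    tips = _codon_tip_partials(sub, tidx)
    P = model.transition_matrices(lengths)
    return generic_log_likelihood(tidx, P, tips, model.codon_frequencies)


@dataclass
class FitResult:
    model: CodonModelM0
    tree: TraitLabeledTree
    log_likelihood: float
    converged: bool
    n_sweeps: int


def fit_model(
    codon_msa: MultipleSequenceAlignment,
    tree: TraitLabeledTree,
    init: CodonModelM0 | None = None,
    freq_model: str = "F3x4",
    estimate_lengths: str = "auto",
    tol: float = 1e-6,
    max_sweeps: int = 500,
) -> FitResult:
    """Maximum-likelihood fit of kappa, omega and branch-length scale.

    Coordinate ascent with bounded Brent line searches per parameter;
    the log-likelihood is non-decreasing across sweeps and iteration
    stops when one full sweep improves it by less than ``tol``.

    ``estimate_lengths``: "scale" rescales the given branch lengths by a
    single factor; "branch" optimizes each branch length (required for
    cladogram guide trees); "auto" picks "scale" when the tree has
    lengths and "branch" otherwise.
    """
    shared = set(codon_msa.species) & set(tree.tip_labels)
    work_tree = tree.prune_to(shared)
    tidx = TreeIndex(work_tree)
    sub = codon_msa.subset(tidx.tree.tip_labels)
    tips = _codon_tip_partials(sub, tidx)

    if estimate_lengths == "auto":
        estimate_lengths = "scale" if work_tree.has_lengths else "branch"
    if estimate_lengths == "scale":
        base_lengths = tidx.require_lengths().copy()
    else:
        base_lengths = np.where(
            np.isnan(tidx.lengths), 0.1, np.maximum(tidx.lengths, 1e-4)
        )
        base_lengths[tidx.root] = np.nan

    if freq_model == "F3x4":
        freqs = f3x4_frequencies(sub)
    elif freq_model == "F61":
        freqs = f61_frequencies(sub)
    else:
        raise ValueError("freq_model must be F3x4 or F61")

    init = init or CodonModelM0(codon_frequencies=freqs)
    state = {"kappa": init.kappa, "omega": init.omega, "scale": 1.0}
    lengths = base_lengths.copy()

    def loglik(kappa, omega, lens) -> float:
        model = CodonModelM0(kappa=kappa, omega=omega, codon_frequencies=freqs)
        P = model.transition_matrices(lens)
        return generic_log_likelihood(tidx, P, tips, model.codon_frequencies)

    def current_lengths() -> np.ndarray:
        if estimate_lengths == "scale":
            return base_lengths * state["scale"]
        return lengths

    def objective_for(par: str):
        def f(logv: float) -> float:
            v = float(np.exp(logv))
            if par == "kappa":
                return -loglik(v, state["omega"], current_lengths())
            if par == "omega":
                return -loglik(state["kappa"], v, current_lengths())
            return -loglik(
                state["kappa"], state["omega"], base_lengths * v
            )
        return f

    bounds = {
        "kappa": (np.log(0.01), np.log(100.0)),
        "omega": (np.log(1e-3), np.log(20.0)),
        "scale": (np.log(1e-3), np.log(100.0)),
    }
    pars = ["kappa", "omega"] + (["scale"] if estimate_lengths == "scale" else [])

    best = loglik(state["kappa"], state["omega"], current_lengths())
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        for par in pars:
            res = minimize_scalar(
                objective_for(par), bounds=bounds[par], method="bounded",
                options={"xatol": 1e-6},
            )
            if -res.fun >= best:
                state[par] = float(np.exp(res.x))
                best = -res.fun
        if estimate_lengths == "branch":
            for v in range(tidx.n_nodes):
                if v == tidx.root:
                    continue

                def f_branch(logt: float, v=v) -> float:
                    trial = lengths.copy()
                    trial[v] = float(np.exp(logt))
                    return -loglik(state["kappa"], state["omega"], trial)

                res = minimize_scalar(
                    f_branch, bounds=(np.log(1e-7), np.log(20.0)),
                    method="bounded", options={"xatol": 1e-7},
                )
                if -res.fun >= best:
                    lengths[v] = float(np.exp(res.x))
                    best = -res.fun
        new = loglik(state["kappa"], state["omega"], current_lengths())
        if sweeps > 1 and new - previous < tol:
            converged = True
            previous = new
            break
        previous = new
    if not converged:
        log.warning("fit_model: not converged after %d sweeps", sweeps)

    final_lengths = current_lengths()
    fitted_tree = tidx.tree.copy()
    for v, nid in enumerate(tidx.ids):
        if v != tidx.root:
            fitted_tree.node(nid).length = float(final_lengths[v])
    model = CodonModelM0(
        kappa=state["kappa"], omega=state["omega"], codon_frequencies=freqs
    )
    return FitResult(model, fitted_tree, best, converged, sweeps)


# ---------------------------------------------------------------------------
# Ancestral state containers


@dataclass
class AncestralStates:
    """Reconstructed amino-acid states at every node over filtered sites."""

    method: str  # "parsimony" | "marginal_ML"
    tree: TraitLabeledTree
    site_columns: tuple[int, ...]  # protein alignment columns reconstructed
    best: dict[str, np.ndarray]  # node id -> array of single-char states
    posterior: dict[str, np.ndarray]
    ambiguous: dict[str, np.ndarray]

    @property
    def n_sites(self) -> int:
        return len(self.site_columns)

    def states(self, node_id: str) -> str:
        return "".join(self.best[node_id])

    def to_frame(self):
        import pandas as pd

        rows = []
        for nid in self.best:
            for k, col in enumerate(self.site_columns):
                rows.append(
                    (nid, col + 1, self.best[nid][k], self.posterior[nid][k])
                )
        return pd.DataFrame(rows, columns=["node", "column", "state", "posterior"])


# ---------------------------------------------------------------------------
# Fitch parsimony


_AA_BIT = {aa: 1 << i for i, aa in enumerate(AMINO_ACIDS)}
_FULL_SET = (1 << len(AMINO_ACIDS)) - 1


def fitch_asr(protein_msa: MultipleSequenceAlignment, tree: TraitLabeledTree
              ) -> AncestralStates:
    """Parsimony reconstruction over amino acids (unit-cost Sankoff).

    Up and down cost passes give, per node and site, the minimum number
    of changes with that node fixed to each state; the states attaining
    the global minimum are exactly those that appear in some
    maximum-parsimony reconstruction.  A node/site is *ambiguous* when
    more than one state does, in which case ties break alphabetically
    for the reported best state (and replacement calling skips it).
    Gap or unknown tip characters are treated as missing data.
    """
    shared = set(protein_msa.species) & set(tree.tip_labels)
    work = tree.prune_to(shared) if shared != set(tree.tip_labels) else tree
    tidx = TreeIndex(work)
    seqs = {name: seq for name, seq in protein_msa.records}
    n_sites = protein_msa.length
    k = len(AMINO_ACIDS)
    aa_idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    INF = 1e9

    up = np.zeros((tidx.n_nodes, n_sites, k))
    for v in range(tidx.n_nodes):
        if tidx.is_tip[v]:
            seq = seqs[tidx.ids[v]]
            cost = np.zeros((n_sites, k))
            for s, ch in enumerate(seq):
                if ch in aa_idx:
                    cost[s, :] = INF
                    cost[s, aa_idx[ch]] = 0.0
            up[v] = cost
        else:
            acc = np.zeros((n_sites, k))
            for c in tidx.children[v]:
                msg = np.minimum(up[c], up[c].min(axis=1, keepdims=True) + 1.0)
                acc += msg
            up[v] = acc

    down = np.zeros((tidx.n_nodes, n_sites, k))
    for v in reversed(range(tidx.n_nodes)):  # preorder
        kids = tidx.children[v]
        if not kids:
            continue
        msgs = {
            c: np.minimum(up[c], up[c].min(axis=1, keepdims=True) + 1.0)
            for c in kids
        }
        for c in kids:
            t = down[v].copy()
            for w in kids:
                if w != c:
                    t += msgs[w]
            down[c] = np.minimum(t, t.min(axis=1, keepdims=True) + 1.0)

    best: dict[str, np.ndarray] = {}
    posterior: dict[str, np.ndarray] = {}
    ambiguous: dict[str, np.ndarray] = {}
    aa_arr = np.array(list(AMINO_ACIDS))
    for v in range(tidx.n_nodes):
        nid = tidx.ids[v]
        if tidx.is_tip[v]:
            best[nid] = np.array(list(seqs[nid]))
            posterior[nid] = np.ones(n_sites)
            ambiguous[nid] = np.zeros(n_sites, dtype=bool)
            continue
        total = up[v] + down[v]
        mins = total.min(axis=1, keepdims=True)
        optimal = total <= mins + 1e-9
        amb = optimal.sum(axis=1) > 1
        states = aa_arr[optimal.argmax(axis=1)]  # alphabetically first optimum
        best[nid] = states
        posterior[nid] = np.where(amb, 0.0, 1.0)
        ambiguous[nid] = amb
    return AncestralStates(
        method="parsimony",
        tree=work,
        site_columns=tuple(range(n_sites)),
        best=best,
        posterior=posterior,
        ambiguous=ambiguous,
    )


def fitch_min_changes(protein_msa: MultipleSequenceAlignment,
                      tree: TraitLabeledTree) -> np.ndarray:
    """Per-site minimum substitution counts from the Fitch bottom-up pass."""
    shared = set(protein_msa.species) & set(tree.tip_labels)
    work = tree.prune_to(shared) if shared != set(tree.tip_labels) else tree
    tidx = TreeIndex(work)
    seqs = {name: seq for name, seq in protein_msa.records}
    n_sites = protein_msa.length
    sets = np.zeros((tidx.n_nodes, n_sites), dtype=np.int64)
    changes = np.zeros(n_sites, dtype=int)
    for v in range(tidx.n_nodes):
        if tidx.is_tip[v]:
            sets[v] = [_AA_BIT.get(ch, _FULL_SET) for ch in seqs[tidx.ids[v]]]
        else:
            acc = sets[tidx.children[v][0]].copy()
            for c in tidx.children[v][1:]:
                inter = acc & sets[c]
                union = acc | sets[c]
                changes += inter == 0
                acc = np.where(inter != 0, inter, union)
            sets[v] = acc
    return changes


# ---------------------------------------------------------------------------
# Marginal ML reconstruction


def marginal_asr(
    codon_msa: MultipleSequenceAlignment,
    tree: TraitLabeledTree,
    model: CodonModelM0,
    site_columns: Sequence[int] | None = None,
    collapse: str = "amino_acid",
) -> AncestralStates:
    """Marginal posterior reconstruction under a fitted M0 model.

    ``site_columns`` selects protein-alignment columns (0-based) to
    reconstruct, e.g. the gap-filtered set; default is every codon.
    ``collapse='amino_acid'`` sums codon posteriors within amino acids
    before taking the argmax; ``collapse='codon'`` argmaxes over codons
    first and then translates (sensitivity mode).
    """
    shared = set(codon_msa.species) & set(tree.tip_labels)
    work = tree.prune_to(shared) if shared != set(tree.tip_labels) else tree
    tidx = TreeIndex(work)
    lengths = tidx.require_lengths()
    sub = codon_msa.subset(tidx.tree.tip_labels)
    n_sites_all = sub.length // 3
    cols = tuple(site_columns) if site_columns is not None else tuple(range(n_sites_all))

    tips = _codon_tip_partials(sub, tidx)[:, cols, :]
    P = model.transition_matrices(lengths)
    post_codon = generic_marginal_posteriors(
        tidx, P, tips, model.codon_frequencies
    )

    collapse_m = aa_collapse_matrix()
    post_aa = post_codon @ collapse_m  # (nodes, sites, 20)

    seqs = {name: seq for name, seq in sub.records}
    best: dict[str, np.ndarray] = {}
    posterior: dict[str, np.ndarray] = {}
    ambiguous: dict[str, np.ndarray] = {}
    aa_arr = np.array(list(AMINO_ACIDS))
    codon_aa = np.array([translate_codon(c) for c in SENSE_CODONS])
    for v in range(tidx.n_nodes):
        nid = tidx.ids[v]
        if tidx.is_tip[v]:
            observed = np.array(
                [translate_codon(seqs[nid][3 * c: 3 * c + 3]) for c in cols]
            )
            best[nid] = observed
            posterior[nid] = np.ones(len(cols))
            ambiguous[nid] = np.zeros(len(cols), dtype=bool)
            continue
        if collapse == "codon":
            arg = post_codon[v].argmax(axis=1)
            states = codon_aa[arg]
            probs = post_aa[v][np.arange(len(cols)),
                               [AMINO_ACIDS.index(a) for a in states]]
        else:
            arg = post_aa[v].argmax(axis=1)
            states = aa_arr[arg]
            probs = post_aa[v][np.arange(len(cols)), arg]
        best[nid] = states
        posterior[nid] = probs
        ambiguous[nid] = np.zeros(len(cols), dtype=bool)
    return AncestralStates(
        method="marginal_ML",
        tree=work,
        site_columns=cols,
        best=best,
        posterior=posterior,
        ambiguous=ambiguous,
    )
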