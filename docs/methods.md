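# Methods

This note records the models, conventions and numerical choices behind
`chloroconv`, in enough detail that a maintainer can predict its
behaviour on edge cases without reading the source.

## Reference branches

Given a rooted tree and a tip trait map (C3 / C4 / outgroup), a
*reference branch* is the branch subtending the MRCA of a **maximal**
clade whose tips are all one ingroup type. Singleton tips qualify
(terminal branches are valid reference branches); outgroup tips never
contribute; the root itself carries no branch, and a fully
monochromatic ingroup is accepted with a warning rather than rejected.

Maximality is relative to the *sampled* tree, which can be wrong when
the true phylogeny contains intervening lineages that were not
sequenced. Because that evidence is external, the tool never infers
it: **forced splits** — tip sets that must each become their own
reference branch — are configuration. A forced set must be a clade; a
maximal clade containing forced subsets is replaced by the forced
sub-branches plus the maximal monochromatic remainder. Branch ids are
uppercase letters assigned in depth-first order with children ordered
by their lexicographically smallest descendant tip, so ids are
invariant to tip order in the source newick.

All unordered pairs of reference branches are compared; with n4 C4 and
n3 C3 branches there are n4(n4−1)/2 C4:C4, n3(n3−1)/2 C3:C3 and n3·n4
C3:C4 pairs. Pairwise contrasts between branches are treated as
independent observations, in the spirit of phylogenetically
independent contrasts: replacements on one pair of branches are
independent of replacements on another.

## Ancestral reconstruction

**Codon model.** M0: rates q_ij = π_j·{1,κ}·{1,ω} for single-nucleotide
codon changes (transition vs transversion, nonsynonymous vs
synonymous), zero otherwise, diagonal filled to zero row sums, scaled
so the equilibrium substitution rate is 1 (branch lengths in expected
substitutions per codon). Stop codons are excluded (61 sense codons);
the genetic code is translation table 11 (plastid), identical to the
standard code over sense codons. Codon frequencies default to F3x4
computed from the data (F61 by flag); frequencies are floored at 1e-10
and renormalized so the chain stays irreducible. The matrix is
reversible, so P(t) comes from a symmetric eigendecomposition, clipped
at zero and row-renormalized against round-off.

**Likelihood and marginal states.** Felsenstein pruning with per-site
rescaling (log-scale accumulators) gives the likelihood; an
inside–outside (up/down) pass gives marginal posteriors at every node.
Both are implemented over an arbitrary finite state space and are
checked against brute-force enumeration on small two-state fixtures.
Codon posteriors are summed within amino acids **before** the argmax,
because replacements are defined on amino acids (argmax over codons
followed by translation is available as a sensitivity flag). Tips
always report their observed residues. Gap codons (`---`) are missing
data (uniform partial likelihood); partially gapped codons and internal
stops are errors.

**Fitting.** κ, ω and either a global branch-length scale (when the
guide tree has lengths) or every branch length (cladogram guide trees)
are estimated by coordinate ascent with bounded Brent searches on log
scale (κ ∈ [0.01, 100], ω ∈ [0.001, 20]); a sweep that improves the
log-likelihood by less than 1e-6 stops the iteration (cap 500 sweeps;
non-convergence is reported, not silent). Parameter recovery on
simulated data (64+ tips × 500 codons) is within 20% for κ and ω.

**Parsimony path.** Unit-cost Sankoff up/down passes give, per node and
site, the minimum change count with the node fixed to each state. The
states attaining the global minimum are exactly those appearing in some
maximum-parsimony reconstruction; a node/site with more than one such
state is flagged *ambiguous*, ties break alphabetically for the
reported state, and ambiguous nodes are excluded from replacement
calling. This is deliberately stricter than reporting the first-pass
Fitch set: the flag marks genuine MPR non-uniqueness, not transient
ambiguity that the downpass resolves.

**Site filtering and coordinates.** Columns with a gap in any ingroup
species are excluded (a flag extends the rule to all species). Site
labels use the 1-based protein coordinate of a configurable reference
species (Zea mays in the emulated study); where the reference species
itself has a gap the site keeps an alignment-column fallback label
`col:<n>` and still counts. The tree is pruned per gene to the species
with data; suppressed unifurcations sum their branch lengths.

## Classification and aggregation

Two replacements at one site on two branches of a pair form one event:
convergent iff the derived residues match (parallel iff the ancestral
residues also match, true-convergent otherwise), non-convergent iff
the derived residues differ — ancestral states are irrelevant for the
convergent/non-convergent dichotomy. Chemical similarity of residues
is deliberately ignored (strict convergence definition). Only
reference branches are scanned; changes inside the subtended clades
are ignored, which biases the analysis conservative.

Counting units are deliberately dual: *sites* are distinct (gene,
site) keys with at least one event of a class in a category; *events*
are pairwise comparisons. A site may carry both convergent and
non-convergent events through different pairs. "Unique" site/gene
counts restrict to those with same-class events in no other category;
a stricter variant (no events of any kind elsewhere) is computed as
well, since the two readings differ and published tallies do not pin
one down.

*Type-specific conserved convergent sites* (the candidate-adaptive
set) require at least `min_branches` (default 3) branches of one type
sharing the same derived residue with **no other replacement of any
kind** at the site — a single extra replacement on any other branch
disqualifies it.

## Exact statistics

* **Fisher** — full hypergeometric enumeration conditional on both
  margins; the two-sided p sums probabilities ≤ observed × (1 + 1e-12)
  (the relative tie tolerance guards against float noise in equal-mass
  tables). Degenerate all-zero tables give p = 1 with a warning.
* **Boschloo** — ordering statistic is the Fisher p of the same
  sidedness; p = sup over π ∈ (0,1) of the binomial probability of the
  rejection region {tables with Fisher p ≤ observed}. The sup is taken
  on a 1,000-point uniform grid and refined by golden-section search
  around the top three local maxima of the grid profile; doubling the
  grid moves the battery p-values by < 1e-4, and agreement with a
  10,001-point enumeration oracle is ≤ 1e-6. Endpoints are degenerate
  (all-failure/all-success mass) and can only matter when the observed
  Fisher p is 1, where p = 1 anyway. Boschloo ≤ Fisher is asserted on
  every call. scipy's `boschloo_exact` shares the ordering statistic
  but differs in the third decimal on some tables (its nuisance
  optimization and tie inclusion), so the enumeration oracle — not
  scipy — is the reference in tests.
* **Mann–Whitney U** — exact permutation distribution of the rank sum
  via a shift-algorithm dynamic program over doubled midranks (exact
  with ties, conditional on the observed tie pattern); two-sided
  p = min(1, 2·min(tail p)). Used for the branch-length bias control
  on per-category pair length sums.

No multiple-testing correction is applied by default (raw p-values are
reported, as is conventional for this analysis); Benjamini–Hochberg is
available behind a flag for multi-gene scans.

## Synthetic data

The generator emulates the study conditions, not any particular
dataset: a Yule-backbone tree of monochromatic clades (types assigned
so no backbone subtree is single-type, by seeded rejection sampling;
with extreme type ratios a perfect assignment may not exist and the
best attempt is kept with a warning), two basal outgroup tips, and
codon sequences evolved by per-branch transition-probability sampling
under M0 (endpoint states only — sufficient because the analysis never
looks inside a branch). Defaults: κ = 2, ω = 0.2, uniform codon
frequencies, 300 codons, exponential branch lengths of mean 0.02
(backbone) / 0.01 (within clades) — short branches typical of
intra-clade chloroplast divergence, keeping the simulations in the
low-homoplasy regime the method assumes.

**Injections** plant convergence: at a designated site the root
receives a codon of a chosen ancestral residue, background evolution
at that site is suppressed, and each designated reference branch
substitutes deterministically to a codon of the target residue
(injections operate at codon level so codon-model reconstruction and
amino-acid truth stay consistent; a noisy mode keeps background
evolution on for stress tests). Ground truth — all node sequences and
per-branch replacement events — is exported. Everything is
bit-reproducible from the seed.

What passing the synthetic battery does *not* show: the generator has
no indels, no among-site rate variation, no alignment error, no
paralogy, and no hemiplasy (introgression / incomplete lineage
sorting), all of which exist in real data. Recovery results on
simulations therefore bound method error, not data error. Injections
covering a majority of lineages are intentionally not used in the
recovery tests — when most clades carry the derived state the true
ancestral state is statistically unidentifiable and reconstruction
legitimately flips.

## The packaged study fixture

The per-site replacement data of the emulated study are not
redistributable here, so the packaged fixture is **synthetic**,
generated in code (`chloroconv.fixtures`): a 64-tip ladder tree (43 C4
/ 19 C3 ingroup tips in 22 clades with four forced sister pairs, 2
outgroups) whose reference branches come out as 13 C4 + 9 C3, and a
replacement table constructed so the classification reproduces the
emulated headline counts exactly (217 convergent sites 104/120/34, 201
non-convergent 96/121/39, twelve C4-specific sites in 7 genes, seven
C4 branches sharing NdhH H18Q, exactly two true-convergent sites MatK
205 / NdhF 636). Reference-branch lengths span the same range in both
types by construction, encoding the studied condition that pair length
sums do not differ between categories (Mann–Whitney p > 0.5) — the
length-bias control must pass on the fixture because the emulated
system had no length bias. Cell-by-cell reproduction of every
published table is *not* encoded; quantities outside the headline set
(per-pair distributions, unique-count rows) are arbitrary deterministic
arrangements.

## Pipeline and determinism

Two entry modes: *full* (alignments → ASR → replacement calling) and
*table* (precomputed replacement table), because everything downstream
of the replacement table is exactly reproducible while reconstructions
are only approximately reproducible across implementations. Stages
abort with stage-tagged diagnostics and partially written outputs are
removed. All randomness flows through one seeded generator; reruns
with identical configuration are byte-identical, and a manifest
records version, seed and config digest. In the tests and the
acceptance script, problem sizes (tip counts, codon counts, replicate
counts, nuisance-grid sizes) are chosen so the full battery completes
in a few minutes on one core while keeping every estimate's Monte
Carlo error well inside the asserted margins.

## Known limitations

* M0 only: no among-site rate variation (NSsites), branch models, or
  positive-selection testing; marginal (not joint) reconstruction.
* The convergent/non-convergent dichotomy ignores residue chemistry by
  design; biochemically conservative changes count as non-convergent.
* Reference-branch maximality depends on taxon sampling; forced splits
  shift that responsibility to the user, they do not remove it.
* Hemiplasy can masquerade as convergence; nothing in the method
  distinguishes them.
* The exact Mann–Whitney DP is quadratic in total rank mass; for
  samples beyond a few hundred values an asymptotic test would be the
  right tool instead.
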