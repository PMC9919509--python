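# Methods

This note documents the models, conventions and defaults the package
implements, the design choices made where the design was genuinely open, and
what the synthetic fixtures do and do not demonstrate.

## Character matrices

A matrix is a taxa × characters grid in which each cell is a non-empty state
set (singleton or polymorphic), a finite real (continuous characters), or
one of two unscored markers: MISSING (`?`) and INAPPLICABLE (`-`). The two
markers are preserved distinctly in storage and I/O but treated identically
in inference — as full ambiguity. A taxon with no observation cannot create
parsimony steps, cannot falsify the presence of a state, and contributes an
all-ones partial to the likelihood. Character ids are 1-based everywhere a
user sees them, matching the anatomical numbering convention of published
character lists.

The NEXUS dialect accepted is the one morphological supplements use in
practice: a `DATA`/`CHARACTERS` block with `STANDARD` symbols, `(01)`-style
polymorphisms, continuous characters written as whitespace-separated decimal
tokens inside the same matrix (a discrete-coded fallback is accepted for the
same columns), and an `ASSUMPTIONS` block whose `TYPESET ... ord:` list
flags ordered characters and whose `CHARSET continuous` names the continuous
block. Interleaved matrices are deliberately rejected rather than guessed
at. Per-character state counts are inferred from the observed cells (NEXUS
itself only declares a global symbol list); a character listed as ordered is
floored at three states, since ordering is meaningless below that.

## Parsimony optimisation

All discrete optimisation runs through a single generalised Sankoff dynamic
programme over per-node cost vectors. Unordered characters use unit costs —
on binary trees this reproduces Fitch counts exactly, and on polytomies the
cost-vector recursion remains exact where the classical
intersection/union shortcut needs special-casing, which is why Fitch is
implemented as Sankoff rather than the other way round. Ordered characters
use |i−j| costs, the standard formalisation of characters whose anatomical
transitions pass through identified intermediates. Continuous characters use
linear (Manhattan) parsimony, computed exactly as Sankoff over the sorted
unique tip values with |vᵢ−vⱼ| costs: for L1 costs an optimal assignment
always exists with every internal node at a tip value, so the discretisation
is not an approximation. Per-node reconstructions for continuous characters
are reported as the [min, max] interval of optimal candidate values.

Node MPR sets are computed by a down-pass/up-pass: a state is in a node's
set iff fixing the node to that state admits a completion achieving the
global minimum. The spec of a most-parsimonious labelling used throughout is
the exact one — root state optimal, every child state locally optimal given
its parent — which characterises the full set of optima for tree-decomposable
costs. ACCTRAN/DELTRAN-style unique resolutions are *not* used for
classification, because the diagnosis rules below reason explicitly from
ambiguity; a single deterministic resolution (lowest optimal state at each
step) is retained only for human-readable change lists.

Independent origins of a state are counted by a second DP restricted to
optimal labellings: a branch counts when its child bears the state and its
parent does not, and a root bearing the state counts as one ancestral
origin, so (min, max) answers "how many times does this state arise?" across
all MPRs. Homoplasy is summarised per character by the consistency index
CI = m/s and retention index RI = (g−s)/(g−m), with m the minimum conceivable
steps on any tree (states-needed − 1 for unordered, observed range for
ordered; polymorphic cells satisfied greedily), s the observed steps and g
the steps on a star tree. RI is reported as null when g = m (the character
cannot retain anything), and CI as 1 for constant characters.

## Synapomorphy diagnosis

For a clade C, character state a is classified by three ordered tests:

1. **ubiquity** — every *scored* member of C has a (polymorphic cells count
   as presence by default; a stricter sole-state mode is available);
   unscored members are listed in the notes but never falsify;
2. **unambiguous ancestral reconstruction** — {a} is the entire MPR set at
   C's most recent common ancestor;
3. **sister absence** — a is in no MPR set at the sister node; when the
   parent is a polytomy the test must hold against every co-child, and when
   C spans the root the test is recorded as not evaluable.

A state passing all three and *not* unambiguously present at the MRCA's
parent is an unreversed synapomorphy ('\*'). Retention takes precedence: a
state reconstructed unambiguously at both the MRCA and its parent is a
retained plesiomorphy ('§') no matter how derived the sister is, because
nothing originated on the clade's stem — without this precedence an ancestral
state would be starred for a clade whose sister fixed the alternative.
Ubiquitous states failing test 2 or 3 are kept as explicit
`ambiguous_not_synapomorphy` records (this is the situation missing data
typically creates: the single required change can sit on the scored tip's
own branch instead of the stem, widening the MRCA set). States present in at
least 80% of scored members are kept as near-ubiquitous diagnostics with
their exceptions enumerated; the 0.8 threshold is a package default chosen
to admit the "absent in a few convergently specialised taxa" pattern while
excluding genuinely variable states, and it is a keyword argument. Every
record carries its criterion audit, so any classification — positive or
negative — can be traced to the test that decided it.

A tree-wide uniqueness scan flags unreversed synapomorphies whose state has
exactly one origin in every MPR over the whole optimisation tree including
outgroups; on realistically homoplastic data this table is expected to be
sparse or empty.

## Likelihood model and fossil placement

Discrete characters enter an Mk likelihood: per character, a k-state
symmetric CTMC scaled to one expected change per unit branch length, so
P(same) = 1/k + (k−1)/k·e^(−kt/(k−1)). Rate variation across characters uses
a 4-category discrete gamma with equal-probability bins represented by their
category means (shape α shared across characters). Ascertainment is handled
by variable coding: each character's likelihood is divided by (1 − P_inv),
where P_inv — the probability of an invariant pattern, mixed over rate
categories — rides along the same pruning pass as k pseudo-characters with
basis partials. Polymorphic cells contribute partials with ones at each
observed state. Continuous characters are always excluded from the
likelihood. The pruning recursion equals brute-force enumeration over
internal states to machine precision (the test suite and acceptance script
verify ~1e−16 relative error against an independent enumerator).

Fossil placement holds the extant backbone fixed — a hard constraint, as in
scaffolded morphological analyses; any fossil with a known position is part
of the backbone rather than a floating tip. The sampler's state is: one
attachment (host branch, position along it, pendant length) per floating
fossil, all branch lengths, and α. Moves are (i) re-attach a uniformly
chosen fossil to a uniformly chosen backbone-or-other-fossil-pendant branch
with fresh position and prior-drawn pendant (proposals that would create an
attachment cycle are rejected), (ii) a multiplier on one branch length, and
(iii) a multiplier on α. Chains are Metropolis-coupled with incremental
heating βⱼ = 1/(1 + jT), T = 0.1, with one adjacent-pair swap proposal per
generation; two independent runs are pooled after discarding the first 25%
of each run's samples. Priors: exponential(rate 10) on all branch and
pendant lengths and exponential(1) on α — common defaults for unconstrained
morphological analyses, stated here as assumptions and configurable;
attachment is uniform over eligible branches. Everything is driven by one
integer seed and is exactly reproducible.

Summaries report, per fossil, the posterior frequency of each backbone
attachment branch (fossils attached to other fossils' pendants resolve to
their ultimate backbone branch) and the posterior probability of membership
in each registered clade, crown and total separately: attachment inside the
clade's crown subtree is crown membership; attachment to the clade's stem
branch is total-clade membership only. Nesting monotonicity of these BPPs
holds exactly by construction. Group-level membership (all fossils of a
named set inside a clade) is available because joint posteriors are not
products of marginals. The consensus tree is a strict 50% majority-rule
consensus (exactly the splits above half frequency, no extra compatible
splits), built through dendropy and annotated with split frequencies; the
between-run average standard deviation of split frequencies (for splits
above 10%) is reported as a convergence diagnostic, not enforced.

An exhaustive parsimony attachment scan complements the sampler: using the
Sankoff down/up vectors of the backbone, the extra steps of attaching the
fossil to every branch are computed in closed form without re-optimisation,
ranked deterministically (ties broken by postorder index). An entirely
unscored fossil ties everywhere and is flagged.

## Synthetic data

The generator evolves characters along a seeded birth–death scaffold scaled
to total edge length 1, so a character's rate equals its expected number of
changes across the whole tree; rates are lognormal(ln 6, 0.6) by default —
several changes per character, the homoplasy regime real matrices of this
kind show. Unordered characters jump uniformly among the other states;
ordered characters take ±1 stepping-stone jumps. Planted characters change
exactly once, on the named clade's stem branch, and are the ground truth for
synapomorphy recovery; a homoplasy-boost multiplier raises selected
characters' rates for the false-positive audit. Continuous characters follow
Brownian motion (σ² = 1 by default) purely to exercise linear parsimony.
Fossil rows evolve from the child end of a named branch along a short
pendant and are masked to a stated missing fraction. The default study-scale
fixture has 142 extant tips, 49 discrete + 5 continuous characters, ~20% of
multistate characters ordered, 10 planted markers and 11 fossils at 40–80%
missingness.

What the fixtures do not emulate: correlated character evolution,
asymmetric or state-dependent transition rates, non-random (anatomically
clustered) missingness in fossils, and scoring error. Perfect recovery of
planted markers therefore demonstrates the correctness of the machinery
under the stated generating model, not the expected accuracy on real
matrices, where homoplasy and non-random preservation will lower support.

## Problem sizes and numerical choices

The test suite and acceptance script run the samplers at reduced scale —
20-tip backbones with 200k generations for prior recovery, 4k generations
for the placement-recovery replicates, and ~1.5k generations at the 142-tip
study scale — sizes chosen so the full suite completes in minutes while the
checks they support (prior recovery, planted-placement recovery, structural
invariants) are already decisive at that scale. Posterior summaries at full
matrix scale would use the same code paths with more generations.

Floating-point ties in the Sankoff DPs use an absolute tolerance of 1e−9
(costs are integers or sums of input values, so this is far below any true
gap). The attachment scan rounds added steps to 9 decimals before ranking.
The likelihood returns −inf for any zero pattern probability rather than
raising inside the sampler. Degenerate inputs are defined, not special-cased:
an all-missing column optimises to zero steps with full MPR sets; an
all-missing fossil is flagged and recovers its prior; a missing-fraction of
1 is allowed and flagged; an empty record list is a report-writing error
rather than an empty file.

## Known limitations

Likelihood pruning is unscaled; for matrices beyond a few hundred taxa
per-node rescaling would be needed. The sampler proposes no joint moves, so
mixing over strongly co-placed fossil sets relies on the heated chains. The
m used in CI is exact for unit and ordered costs but greedy for polymorphic
cells under exotic cost matrices. `Halfcompat` consensus is implemented as
strict majority rule; compatible sub-majority splits are never added.
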