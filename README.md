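# morphplace

Morphological phylogenetics on a fixed molecular scaffold: parsimony
character optimisation, rule-based synapomorphy diagnosis, and
backbone-constrained Bayesian placement of fragmentary fossils.

## The problem

Large molecular phylogenies of diverse clades (the motivating case is crown
passerine birds) are well resolved, but fossils preserve only morphology —
often a single skeletal element such as the carpometacarpus, scored as a few
dozen discrete and continuous characters with heavy missing data. Two
questions follow:

1. **Which character states diagnose which clades?** Given a character
   matrix and a fixed, phylogenomically-resolved backbone, which derived
   states are *unreversed synapomorphies* of a named clade (present in all
   sampled members, reconstructed unambiguously at the clade's ancestral
   node, and absent at the sister node), and which are merely retained
   plesiomorphies or homoplastic noise?
2. **Where do the fossils go?** Holding the extant backbone fixed, what is
   the posterior probability that a fragmentary fossil belongs to each named
   clade (crown and total-clade membership treated separately)?

`morphplace` implements both analyses as a tested, reusable library with a
thin CLI, plus a seeded synthetic-data generator so every stage is testable
without any external data.

## Models and algorithms

* **Parsimony optimisation** — one generalised Sankoff dynamic programme
  over per-node cost vectors, exact on polytomies: unit costs for unordered
  characters (Fitch counts), |i−j| costs for ordered multistate characters,
  and linear (Manhattan) parsimony for continuous ratios (exact via Sankoff
  over the sorted tip values). A down-pass/up-pass yields full MPR
  (most-parsimonious-reconstruction) state sets per node, not a single
  ACCTRAN/DELTRAN resolution; a second DP restricted to optimal labellings
  gives the minimum and maximum number of independent origins of any state,
  and consistency/retention indices (CI = m/s, RI = (g−s)/(g−m)) quantify
  homoplasy per character.
* **Synapomorphy diagnosis** — each (clade, character, state) triple is
  classified as `unreversed_synapomorphy` ('\*'), `retained_plesiomorphy`
  ('§'), `near_ubiquitous_diagnostic`, `ambiguous_not_synapomorphy`,
  `homoplastic` or `absent`, with the full criterion audit stored on every
  record. Missing cells never falsify presence but are listed.
* **Bayesian fossil placement** — the Mk model (k-state symmetric CTMC, one
  expected change per unit branch length) with 4-category discrete-gamma
  rate variation and *variable coding* (likelihood conditioned on characters
  being variable). Extant relationships are a hard constraint; the sampler's
  only topology move re-attaches a floating fossil to a backbone or
  fossil-pendant branch. Metropolis-coupled chains (incremental heating,
  temperature 0.1), multiple independent runs, 50% majority-rule consensus,
  per-branch attachment posteriors, crown/total clade-membership BPPs and an
  ASDSF-style between-run convergence diagnostic. An exhaustive parsimony
  attachment scan provides a fast deterministic complement.
* **Synthetic data** — Mk / stepping-stone character evolution with
  lognormal rate heterogeneity on simulated birth–death scaffolds scaled to
  total length 1, planted single-origin clade markers, Brownian continuous
  characters, and fossil rows evolved from known branches and masked to a
  stated missingness. Fully seeded.

## Worked example

```python
import morphplace as mp

# synthetic 20-tip scaffold; character 7 planted as a marker of clade_02
sc = mp.simulate_scaffold(20, seed=3)
cfg = mp.SimulationConfig(tree=sc, n_chars=40, n_continuous=0, seed=3,
                          planted=[mp.PlantedEvent(clade="clade_02", char_id=7)])
matrix, truth = mp.simulate_matrix(cfg)

recon = mp.optimise_matrix(matrix, sc.tree)
for rec in mp.diagnose_clade("clade_02", recon, matrix, sc):
    if rec.classification == "unreversed_synapomorphy":
        print(f"clade_02: char {rec.char_id}({rec.state}){rec.glyph}"
              f"  origins {rec.min_origins}-{rec.max_origins}")
h = mp.homoplasy_indices(recon[7], matrix.column(7))
print(f"char 7: steps={recon[7].steps:.0f}  CI={h.ci:.2f}")

# a fossil evolved on clade_02's first daughter branch, half the cells masked
ti = truth.tree_index
branch = ti.children[ti.mrca(sorted(sc.clades["clade_02"].tips))][0]
matrix = mp.add_fossils(matrix, truth, [mp.FossilSpec(
    name="fossilX", branch_tips=ti.tipset(branch), missing_fraction=0.5)], seed=3)
sc.tip_status["fossilX"] = "floating"

res = mp.run_mcmc(matrix, sc, mp.MkModelConfig(
    generations=4000, sample_every=20, runs=2, chains_per_run=2, seed=5))
summ = mp.summarise(res, sc)
bpp = summ.summaries["fossilX"].clade_bpp
print(f"fossilX in clade_02: crown BPP {bpp[('clade_02','crown')]:.2f}, "
      f"total BPP {bpp[('clade_02','total')]:.2f}; ASDSF {summ.asdsf:.3f}")
```

Output:

```
clade_02: char 7(1)*  origins 1-1
char 7: steps=1  CI=1.00
fossilX in clade_02: crown BPP 0.99, total BPP 1.00; ASDSF 0.009
```

Character 7 is recovered as the clade's starred unreversed synapomorphy with
exactly one origin in every most-parsimonious reconstruction and no
homoplasy (CI = 1); the half-missing fossil is placed inside the crown of
its true clade with posterior probability 0.99, and the two independent runs
agree (average split-frequency deviation below 0.01).

The same steps are available from a shell via `morphplace read-validate /
optimise / diagnose / scan / place / simulate` on NEXUS matrices, Newick
trees and JSON clade tables.

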