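# Methods

## The conformer-generation task as an episodic decision process

A conformer of a covalently bonded molecule is, to a good approximation,
determined by its rotatable-torsion angles: bond lengths and bond angles are
treated as constant, and torsions inside rings as rigid. `torsionrl` casts
conformer generation as a C-step episode. The state is the current conformer
m_i; the action a_{i+1} assigns every rotatable torsion t_j an angle — in the
default discrete mode a bucket index b_j with angle b_j·Δ for a granularity Δ
that divides 360° (default Δ = 60°, so B = 6 buckets per torsion). After the
torsions are set, the structure is locally minimised under the MMFF94 force
field, which generally pulls the dihedrals off the commanded values and into
the nearest well; the relaxed conformer is the next state, is scored by the
reward handler, and after exactly C steps the episode ends with C generated
conformers. The initial state m_0 is a relaxed random conformer: each torsion
is drawn uniformly from the B buckets (uniform on [0, 360) in continuous
mode) from the environment's seeded RNG, then relaxed.

The assumption behind 60° buckets is that distinct low-energy conformers of a
non-ring torsion differ by at least 60° in that torsion; finer granularities
are configurable. A continuous action decode path exists, but the shipped
agents act only in the discrete space.

### Rotatable-bond rule

A bond is rotatable iff it is single, not in a ring, and each of its atoms
has at least one further heavy-atom neighbour. This excludes methyl/hydroxyl
rotors and the ethane C–C bond, none of which produce conformationally
distinct states. The dihedral reference atoms a and d are the lowest-index
heavy neighbours, and torsions are ordered by their central bond (b, c) with
b < c, so the action dimension is deterministic for a given input file.
Dihedrals are signed, IUPAC convention, range (−180°, 180°]; all comparisons
are taken mod 360°.

### Relaxation

MMFF94 as implemented in RDKit, up to 1000 iterations at gradient tolerance
1e-4 (both configurable). Relaxation never increases the energy (asserted to
1e-6 kcal/mol slack) and the energy function is a pure function of the
coordinates. Note that local minima of a torsion surface need not lie at
ideally staggered angles: n-pentane's syn-pentane (g+g−) wells are distorted
to roughly (±95°, ∓65°) by the steric clash between the terminal methyls, and
random starts genuinely relax there. Tests therefore validate relaxed
profiles against minima located by a brute-force grid scan of the rigid
torsion surface rather than against idealized ±60°/180° values.

## Rewards

All three handlers score the post-relaxation conformer:

* **basic_energy**: f(m) = −E(m), with E in kcal/mol.
* **pruning_energy**: 0 for an action vector repeated within the episode,
  −E(m) otherwise. The repeat memory is per-episode.
* **boltzmann**: f(m) = 0 if min{TFD(m, x) : x ∈ S} < threshold, otherwise
  exp(−(E(m) − E0)/kT), after which m joins S. S is the set of conformers
  accepted so far in the episode; pruned conformers are *not* added to S,
  since an existing member already covers their neighbourhood. With an empty
  S nothing is pruned, and molecules without rotatable torsions skip pruning
  entirely (TFD is undefined there).

Defaults: kT = 0.5924 kcal/mol (k_B·298.15 K); TFD threshold 0.05; E0 is the
energy of the episode's initial relaxed conformer, recomputed each episode,
overridable by a fixed per-molecule value (`MolSpec.e0`). Per-episode E0
keeps rewards O(1) across molecules of very different size, at the price of
an episode-level hidden variable the critic cannot observe; with a fixed E0
the return scale is stationary. Both configurations learn in practice.

### Torsional fingerprint deviation

TFD(x, y) is the weighted mean over rotatable torsions of the wrapped
absolute angular deviation normalised by 180°, so it is symmetric, zero iff
the torsion profiles agree mod 360°, and bounded by 1. The weights follow the
standard topological scheme: the most central bond (the non-terminal atom
with the least spread of shortest-path distances, joined to the next most
central bonded atom) gets weight 1, and a torsion whose central bond sits at
path distance d from it gets exp(−β d²), with β anchored so that the weight
at half the maximal central-atom-to-bond distance is 0.1. Weights are
precomputed once per molecule and cached by the reward handler.

## Observations

The agent sees a featurized graph of the current conformer: per-atom
element one-hot over a configurable alphabet (default {C, H, O, N, S, F, Cl,
other}) concatenated with the 3D coordinates in Å; directed edges (both
directions per undirected pair) carrying a bond-type one-hot — single,
double, triple, aromatic, plus a "nonbonded" type for spatial neighbours
within an optional cutoff radius (default 0: covalent bonds only) — and the
Euclidean distance; and the four atom indices of every rotatable torsion for
the per-torsion action heads.

Normalisation modes: translation (centroid to origin; the default),
rotation (principal-axes frame of the coordinate covariance, eigenvalues
descending, each axis sign fixed so the lowest-index atom with a nonzero
projection projects positively — this removes the 8-fold sign ambiguity and
makes rigidly superimposable conformers featurize identically to 1e-6), and
scale (unit RMS radius, with edge distances rescaled). Near-degenerate
covariances (linear molecules) fall back to the deterministic eigensolver
ordering.

## Agents

PPO and A2C over a shared graph policy-value network, implemented on a small
in-repo reverse-mode autodiff engine over numpy arrays. The network: a linear
encoder to hidden width 64, three rounds of edge-conditioned message passing
(message MLP over [h_source ‖ edge features], sum-aggregated at the target,
linear update over [h ‖ aggregate], ReLU throughout), a sum-pooled readout
feeding a two-layer value head, and a shared two-layer MLP over the
concatenated embeddings of each torsion's four atoms producing B logits per
torsion. Parameters are shared across molecules of any size; actions
factorize as independent categoricals per torsion (joint log-probability and
entropy are sums over heads). The final policy layer is initialised at small
scale so the initial action distribution is near-uniform.

Advantages use GAE(γ, λ) with episode-boundary masking and a bootstrapped
value when a rollout truncates an episode. PPO uses the clipped surrogate
(ε = 0.2) over 4 epochs of shuffled minibatches (64) per 200-step rollout
with per-rollout advantage normalisation; A2C takes one full-batch step.
Defaults: γ = 0.99, λ = 0.95, entropy coefficient 0.01, value coefficient
0.5, Adam at 3e-4. All updates abort on non-finite losses; checkpoints
serialize parameters, optimizer moments, config and RNG states, so resuming
reproduces the next iteration bit-stably under fixed seeds.

A seeded uniform-random agent over the B^n action space serves as the
baseline.

## Curriculum

A curriculum is an ordered molecule list with a threshold τ (scalar or
per-molecule) and window w (default 10): after each episode the total reward
enters a rolling window, and when the full window's mean first reaches τ the
environment advances to the next molecule (between episodes, never mid-
episode) and the window clears. The index never decreases and never moves
past the last molecule. The rolling-mean statistic was chosen as the
simplest testable criterion; τ = +∞ never advances, τ = −∞ advances every w
episodes.

## Logging and outputs

Training metrics stream to an append-only CSV/JSONL (iteration, env steps,
mean episode reward, policy/value losses, entropy, optional eval reward on a
held-out second environment, wall time); rows are flushed per line so a
truncated final line cannot corrupt earlier rows. Episodes dump as one V2000
MOL file per conformer plus a JSON manifest (actions, energies, rewards,
pruned flags, total reward, minimum energy, distinct-conformer count at the
TFD threshold); every manifest number is recomputable from the MOL files
plus the config. The ensemble summary table reports per-episode and
aggregate minimum/mean energy, reward totals and distinct counts, and an
optional two-atom distance histogram is re-read from the dumped files.

## Problem sizes, fixtures and what the tests show

Fixtures are n-butane, n-pentane and seeded randomly grown branched alkanes
C_nH_{2n+2} (a uniformly chosen open-valence carbon gains each new carbon;
same seed, same graph and embedding). Test and demo scales are deliberately
small — pentane has 2 torsions and a 36-action joint space that can be
enumerated exhaustively, which gives exact oracles for the environment's
argmax behaviour and the reward bookkeeping. The learning smoke test trains
PPO on pentane (C = 10) in 5,000-step stages up to 50,000 env steps and
compares the stochastic policy's mean total episode reward over 30 episodes
against a seeded random baseline on an identically seeded environment (the
reset stream, and hence the E0 draws, then coincide, making the comparison
paired); the expected margin is ≥1.5× in at least 2 of 3 seeds. An
exhaustive-enumeration experiment bounds the achievable margin at roughly
2× on this molecule, so the bar sits comfortably between noise and ceiling.

Passing these tests demonstrates correct mechanics, exact reward algebra,
and genuine policy improvement on a small alkane; it does not demonstrate
transfer to drug-like molecules, ring-conformer sampling (ring torsions are
rigid by construction), force fields beyond MMFF94, stereochemistry
enumeration, or the wall-clock behaviour of GPU-scale runs.

## Known limitations

* MMFF94 must parameterize the molecule; exotic species raise an
  unsupported-molecule error.
* The Boltzmann seen-set scan is O(C²) TFD evaluations per episode — fine at
  the intended C but quadratic for very long episodes.
* The per-episode E0 default makes returns episode-dependent; critics can
  only learn the average. Fix E0 per molecule when training across episodes
  matters more than cross-molecule reward scale.
* The autodiff engine is single-threaded numpy; it is sized for the small
  graphs of this package, not for large-batch GPU training.
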