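# Methods

This note documents the models and numerical choices behind `foldkit`:
what is computed, under which assumptions, with which defaults, and
what the synthetic test fixtures do and do not demonstrate.

## Representation and units

A conformation is an ordered array of Cα positions (Å), one bead per
query residue. Residue indices are 1-based everywhere, matching the
restraint directive language ("the 3rd and the 14th residue").
Energies and temperatures are dimensionless model units; only relative
energies and their time series are meaningful. Distances are Å
throughout.

Hard geometric invariants for a physically plausible trace:

| invariant | value | where enforced |
|---|---|---|
| virtual bond window | 3.4–4.2 Å | random coils, coil bridges, repaired averages |
| ideal bond length | 3.8 Å | energy minimum, coil growth |
| hard clash (non-adjacent beads, \|i−j\| ≥ 2) | 4.0 Å | same as above |

Template-derived starting structures are exempt: a full-coverage
template is copied verbatim even if its (noisy) geometry violates the
bond window, because the sampler's energy — not a precondition — is
what pushes geometry back to plausibility. `chain.check_conformation`
audits the invariants wherever they are promised.

## Surrogate internal energy

The internal energy is this package's own coarse-grained surrogate; it
is intentionally minimal and is not a statistical potential:

- **bonds**: k_bond · Σ (|b_i| − 3.8)², k_bond = 25;
- **pseudo-bond angles**: k_angle · Σ (θ_i − θ_target)² over interior
  residues whose secondary-structure state is H or E, k_angle = 5;
  targets θ_H = 91°, θ_E = 120° (standard Cα-trace geometry); coil
  residues carry no angle bias, so an uncertain assignment should be
  coil — over-predicting regular structure biases the chain, while
  under-predicting merely leaves it free;
- **excluded volume**: k_rep · Σ max(0, 4.0 − d_ij)² over non-adjacent
  pairs, k_rep = 25.

The constants were chosen once so that, at the dimensionless
temperatures used (1.0–3.5), bond fluctuations are ~0.15–0.25 Å and
the T = 3.5 end of the ladder accepts most moves while T = 1.0 is
nearly frozen. All are configurable via `ChainParams`.

The restraint term is a flat-bottom harmonic: zero inside
[d_min, d_max], weight·(excess)² outside, summed over restraints. It
is continuous in the coordinates and vanishes exactly on the
satisfaction region.

## Restraint generation

Per-pair statistics (min, max, mean, σ) are collected over every
template covering both residues. Conventions and defaults:

- **σ**: population convention (divide by n); `sigma_convention="sample"`
  switches to n − 1.
- **regime gate**: min pairwise template GDT_TS ≥ 0.3 → min/max ranges;
  otherwise mean ± 1σ, with the lower bound floored at 3.0 Å to avoid
  unphysical ranges. The ±1σ width is exact, with no multiplier or
  additive padding.
- **coverage rule**: in the min/max regime a pair must be covered by
  *every* template (a min/max over a partial subset would silently
  narrow the range); in the distribution regime ≥ 2 covering templates
  suffice.
- **pair eligibility**: sequence separation |i − j| ≥ 5 and mean
  distance ≤ 25 Å (defaults, configurable). Short-range geometry is the
  chain model's job; very long distances carry little signal.
- **single template**: bands [d − τ, d + τ] with τ = 1.0 Å by default
  (0.5 Å in the recovery experiments); uncovered residues get no
  restraints and are modeled de novo.
- **edits**: deletions are applied before additions when one directive
  file mixes both, each kind in file order; deleting residues that
  match nothing is a logged no-op; adding on an occupied pair replaces
  it. Both hyphen and en-dash range syntax are accepted.
- default restraint weight 1.0.

## GDT_TS and superposition

Superposition is least-squares rigid (Kabsch via SVD, proper rotations
only), computed over the intersection of residue indices (≥ 3
required). GDT_TS is the mean over cutoffs {1, 2, 4, 8} Å of the
maximal fraction of common residues superposable within the cutoff,
reported as a fraction in [0, 1] so the 0.3 regime gate reads
directly. The maximization uses an iterative seed-extension search:
superpose on a seed subset, collect residues within the cutoff,
re-superpose on them, repeat to a fixed point, take the best fraction
over all seeds and iterations. Seeds are all contiguous 3-, 5- and
7-residue windows (plus the full set); for small common sets (≤ 8
residues) the seeds are instead *all* subsets of size ≥ 3, which makes
the small-instance search exhaustive — the test suite verifies
equality with an independent one-shot all-subset oracle there. Like
every practical GDT implementation, the large-instance search is a
heuristic lower bound on the true optimum.

## Starting structures

- **random coil**: self-avoiding growth with 3.8 Å bonds and clash
  rejection; dead ends trigger limited backtracking (5 beads), then a
  full reseeded restart. Deterministic per seed.
- **templates with gaps**: covered residues take coordinates from the
  first covering template; interior gaps are bridged by linear
  interpolation with a sideways sinusoidal bulge (so short chords still
  get near-3.8 Å steps) plus seeded jitter, then relaxed; uncovered
  tails grow as coil. A gap whose anchors are further apart than
  4.2 Å × (gap + 1) is reported as unbridgeable rather than silently
  stretched.
- **relaxation** (`relax_geometry`): L-BFGS with analytic gradients on
  a smooth bond/clash objective, with an 0.1 Å clash margin so minima
  sit strictly inside the feasible region; anchored beads are held
  fixed. The same routine repairs averaged cluster representatives.

## Replica exchange

Geometric ladder between the endpoints (endpoints exact; a flat range
gives a constant ladder). Defaults: 20 replicas; 3.5–1.0 de novo,
2.0–1.0 consensus. One cycle = one Metropolis sweep per replica (n
proposals, n = chain length) + one exchange sweep over adjacent pairs
of alternating parity. Swap acceptance
min(1, exp[(1/T_a − 1/T_b)(E_a − E_b)]); slots keep their
temperatures and exchange conformations. Moves: single-bead
displacement uniform in a 0.7 Å ball (p = 0.5), crankshaft of the two
beads between anchors i and i+3 by ±25° (p = 0.3), terminal-bead pivot
by ±30° (p = 0.2); each kind is self-inverse in distribution, so the
plain Metropolis rule is valid. "Lowest-energy replica" is resolved per
recording point (the replica currently holding the minimum total
energy), not a fixed index. Each replica owns an RNG stream derived
from the master seed, and exchange decisions use a separate stream, so
changing the replica count does not reshuffle the others' randomness.
Energies are evaluated in full at every proposal — there is no
incremental bookkeeping to drift, and recorded energies equal
recomputation on the recorded snapshots.

The default cycle budget (2000 cycles, i.e. 2000·n proposals per
replica) is a desk-scale choice; tests and the recovery experiments use
smaller, stated budgets.

## Clustering and model selection

Snapshots are embedded as vectors of inter-residue distances with
|i − j| ≥ 3 (rotation/translation invariant) and partitioned by
K-means (scikit-learn, k-means++ seeding, fixed seed, n_init = 10).
Defaults: K = 10 clusters, top 5 reported as models, both configurable;
the pipeline clamps K to the snapshot count.

- **average intra-cluster RMSD**: mean superposed RMSD over all member
  pairs, exact up to 200 members, uniformly subsampled pairs (fixed
  seed) beyond.
- **representative**: medoid (member minimizing summed RMSD to the
  others) when the average RMSD exceeds 2.15 Å, else the coordinate
  average of members superposed onto the medoid, bond-repaired by
  `relax_geometry`. Tight-cluster averages are closer to the members
  than the medoid is (asserted in the test suite); diffuse-cluster
  averages are unphysical, hence the switch.
- **density**: members / (1 + average RMSD) — rises with occupancy and
  tightness. Ties break by size, then lower mean energy, then label.
- **cross-analysis**: pairwise RMSD and GDT_TS matrices over the ranked
  representatives.

## Synthetic fixtures — what they show and what they do not

`fixtures.generate_fixture` builds idealized Cα geometries — a helix
whose radius and rise are solved numerically to sit exactly at the
3.8 Å bond and 91° pseudo-angle targets, a relaxed β-hairpin, and a
self-avoiding random coil — plus noisy, optionally coverage-masked
template copies (isotropic Gaussian noise, default 1.0 Å in demos;
experiments state their own values). Everything is deterministic per
seed.

These fixtures exercise the pipeline's logic (restraint regimes, gap
bridging, recovery, clustering) under controlled conditions. They do
*not* emulate real template sets: real alignment errors are
systematic and correlated, not isotropic noise; real target-template
divergence is structured (domain motions, loop remodeling); and the
surrogate energy has no sequence specificity. Passing the recovery
experiment (a 30-residue helix with an exact template, τ = 0.5 Å,
model_1 within 2 Å and ≥ 95 % restraint satisfaction in ≥ 8/10 seeds,
run at 6 replicas × 800 cycles recording every 10) demonstrates that
restraint generation, sampling and selection compose correctly — not
that the method predicts real protein structures at any particular
accuracy. Dense snapshot recording matters there because model_1 is a
cluster average: averaging ~20 members removes the thermal band-edge
fluctuations individual snapshots carry at T = 1.

## Degenerate inputs and tie-breaks

- Empty restraint set: satisfaction fraction defined as 1.0 with a
  warning; restraint energy 0.
- Sequences: exactly 900 residues accepted, 901 rejected; de novo runs
  longer than 120 residues warn but proceed.
- Absent secondary structure: all-coil default with a warning.
- Multi-model template files: first model only; disordered atoms: first
  altloc; insertion codes: rejected (templates must map cleanly onto
  query numbering); residue identity is not checked against the query,
  only numbering.
- K-means with duplicate snapshots may return fewer than K non-empty
  clusters; empty clusters are dropped before ranking.
- A single replica sits at t_max; n_cycles = 0 records only the start.

## Known limitations

- The surrogate energy cannot fold sequences de novo to native-like
  accuracy; de novo mode is for sampling behaviour studies, not
  prediction.
- GDT_TS for large structures is a heuristic lower bound (as in
  standard implementations).
- The 2.15 Å representative switch and the 0.3 GDT_TS gate are adopted
  protocol constants, not re-derived from data here.
- Cα-only output; no backbone or side-chain reconstruction.
- Single-process execution; replica sweeps are sequential.
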