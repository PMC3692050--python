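# foldkit

Desk-scale, coarse-grained protein structure modeling on a Cα trace:
consensus distance restraints derived from aligned structural templates,
restraint-guided Replica-Exchange Monte Carlo (REMC) sampling, and
trajectory clustering with representative-model selection.

`foldkit` is aimed at structural bioinformaticians who want a small,
fully inspectable implementation of the template-consensus modeling
recipe — every rule, threshold and unit is in plain Python — rather
than production-accuracy structure prediction. The force field is a
deliberately simple surrogate (see *Scope and limitations* below).

## The method

**Inputs.** A query amino-acid sequence (plain text or FASTA, at most
900 residues), an optional per-residue secondary-structure string over
`{H, E, C}` (all-coil is assumed when absent), and zero or more template
structures as PDB files containing at least Cα atoms, residue-numbered
against the query (i.e. pre-aligned).

**Restraints.** Templates define allowed Cα–Cα distance ranges
[d<sub>min</sub>, d<sub>max</sub>] for residue pairs (i, j). Which
ranges are used depends on template agreement, measured by the minimum
pairwise GDT_TS over all template pairs:

- min GDT_TS ≥ 0.3 (*min/max regime*):
  [d<sub>ij</sub><sup>min</sup>, d<sub>ij</sub><sup>max</sup>], the
  extreme distances observed across templates;
- any pair with GDT_TS < 0.3 (*distribution regime*):
  [μ<sub>ij</sub> − σ<sub>ij</sub>, μ<sub>ij</sub> + σ<sub>ij</sub>],
  mean ± standard deviation of the observed distances;
- a single template: a band of half-width τ (default 1 Å) around each
  template distance, with uncovered fragments left restraint-free and
  therefore modeled de novo.

Restraints can be edited with a two-verb directive language:
`A 3 14 7.8 10.12` adds the range 7.8–10.12 Å between residues 3 and
14; `D 55,58,120–160` deletes every generated restraint touching those
residues. During simulation a flat-bottom harmonic penalty
w·(Δd)² applies whenever a restrained distance leaves its range.

**Sampling.** REMC with 20 replicas (default) spread geometrically over
a dimensionless temperature ladder — 3.5–1.0 for de novo runs, 2.0–1.0
for consensus runs. Each cycle performs one Metropolis sweep of local
moves (single-bead displacement, crankshaft, terminal pivot) per
replica, then attempts conformation swaps between adjacent temperatures
with probability min(1, exp[(1/T<sub>a</sub> − 1/T<sub>b</sub>)(E<sub>a</sub> − E<sub>b</sub>)]).
The trajectory records the currently lowest-energy replica together
with its energy, radius of gyration and end-to-end distance.

**Model selection.** Snapshots are clustered with K-means on
rotation-invariant distance features. Each cluster's representative is
the coordinate **average** of its members (superposed onto the medoid,
then relaxed back into physical bond geometry) when the average
intra-cluster RMSD is ≤ 2.15 Å, and the **medoid** otherwise — averages
of diverse clusters are unphysical. Clusters are ranked by density
(members per unit spread, here members/(1 + avg RMSD)); ranked models
get a pairwise RMSD / GDT_TS cross-analysis.

## Worked example

Generate a 30-residue helical toy protein with two mildly perturbed
templates (0.5 Å coordinate noise), then fold it in consensus mode:

```sh
fold fixtures --kind helix --n 30 --perturb 0.5 --templates 2 --seed 7 \
     --out demo_inputs
fold run --mode consensus --seq demo_inputs/seq.fasta \
     --ss demo_inputs/ss.txt \
     --template demo_inputs/template_1.pdb \
     --template demo_inputs/template_2.pdb \
     --replicas 6 --cycles 400 --record-every 10 --k 5 --models 3 \
     --seed 7 --out demo_out
```

prints

```
mode=consensus regime=minmax snapshots=41
model_1: cluster=1 size=14 avg_rmsd=1.404 mode=average
model_2: cluster=4 size=11 avg_rmsd=1.429 mode=average
model_3: cluster=2 size=6 avg_rmsd=0.955 mode=average
```

The two templates agree (pairwise GDT_TS well above 0.3), so restraints
took the min/max form (`regime=minmax`). Of the 41 recorded
lowest-energy-replica snapshots, the densest cluster held 14 members
with an average intra-cluster RMSD of 1.404 Å — below the 2.15 Å
switch, so `model_1` is an average structure. `demo_out/` contains the
Cα trajectory (`trajectory.pdb`, one MODEL per snapshot), per-snapshot
observables (`analysis.tsv`: energy, radius of gyration, end-to-end
distance), the generated restraints with provenance (`restraints.tsv`),
replica-swap events (`swaps.tsv`), cluster statistics
(`clusters.json`), ranked models (`models/model_*.pdb`) and their
cross-analysis matrices (`matrices.tsv`). For example:

```
snapshot  energy      rg         end_to_end
0         418.842931  13.487062  43.678967
1         80.442986   13.397531  43.257279
2         38.299339   13.466061  44.293073
```

(energy in model units; Rg and end-to-end in Å — the start structure
relaxes quickly under the restraints). Runs are deterministic: the same
config and seed reproduce every output byte for byte.

## Scope and limitations

The chain model is Cα-only and off-lattice, with a surrogate internal
energy (harmonic virtual bonds, secondary-structure-biased pseudo-bond
angles, soft-core excluded volume) in dimensionless units — it is not a
statistical potential, and absolute energies are not comparable to any
published force field. No backbone/all-atom reconstruction or
refinement is performed; models are Cα traces. Secondary structure is
taken as input, never predicted. See `docs/methods.md` for the full
model description, parameter table and known limitations.
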