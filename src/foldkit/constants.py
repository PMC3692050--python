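"""Pipeline constants.

Every number that gates a documented behaviour of the modeling protocol
lives here, so the defaults are auditable in one place.  Values marked
"protocol" are part of the published modeling recipe this package
re-implements; values marked "surrogate" belong to this package's own
coarse-grained chain model and are configurable through the parameter
dataclasses that consume them.
"""

# --- protocol constants -------------------------------------------------

#: Hard cap on query sequence length (residues).
MAX_SEQUENCE_LENGTH = 900

#: Recommended upper length for de novo (template-free) runs; longer
#: sequences trigger a validation warning, not an error.
DENOVO_LENGTH_RECOMMENDATION = 120

#: Number of replicas in the replica-exchange ladder.
N_REPLICAS_DEFAULT = 20

#: Minimum pairwise template GDT_TS at or above which consensus restraints
#: use observed min/max distance ranges; below it, mean +/- sigma ranges.
GDT_REGIME_GATE = 0.3

#: Average intra-cluster RMSD (Angstrom) above which the cluster
#: representative is the medoid rather than the average structure.
REPRESENTATIVE_RMSD_SWITCH = 2.15

#: Default temperature ladders (t_max, t_min), dimensionless model units.
DENOVO_TEMP_RANGE = (3.5, 1.0)
CONSENSUS_TEMP_RANGE = (2.0, 1.0)

#: GDT_TS distance cutoffs (Angstrom); the score is the mean over these of
#: the maximal fraction of residues superposable within the cutoff.
GDT_THRESHOLDS = (1.0, 2.0, 4.0, 8.0)

# --- surrogate chain-model constants ------------------------------------

#: Ideal virtual Ca-Ca bond length (Angstrom).
CA_BOND_LENGTH = 3.8

#: Acceptable virtual-bond window (Angstrom) for hard invariant checks.
BOND_WINDOW = (3.4, 4.2)

#: Non-adjacent beads closer than this (Angstrom) count as a hard clash.
HARD_CLASH_DISTANCE = 4.0

#: Ca pseudo-bond-angle targets (degrees) for the secondary-structure bias.
HELIX_PSEUDO_ANGLE_DEG = 91.0
STRAND_PSEUDO_ANGLE_DEG = 120.0
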