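"""Shared physical constants and per-element tables.

All geometric interaction thresholds live here, in one block, so the
criteria used by the detectors and by the directional energy terms are
documented and changed in exactly one place.
"""

#: Coulomb constant, kcal*A/(mol*e^2).
COULOMB_K = 332.0637

#: Bondi van der Waals radii, A (heavy atoms used by the package).
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

# -- geometric interaction criteria (package-wide) ---------------------

#: ligand-residue contact: min side-chain heavy-atom distance, A
CONTACT_CUTOFF = 4.0

#: hydrogen bond: donor...acceptor distance gate, A, and D-H...A angle, deg
HBOND_DMAX = 3.5
HBOND_ANGLE_MIN = 120.0

#: halogen bond: X...A <= vdW sum + this slack, A; C-X...A angle gate, deg
XBOND_SLACK = 0.2
XBOND_ANGLE_MIN = 140.0

#: salt bridge: any carboxylate O ... basic N distance, A
SALT_BRIDGE_DMAX = 4.0

#: contact_diff: a retained contact whose min distance grew by more than
#: this is reported as weakened, A
WEAKENED_DELTA = 0.5

#: descriptive pi-stacking report: ring-centroid distance, A (no energy term)
PI_STACK_DMAX = 5.5

#: hydrogen-bond donor/acceptor element sets (heavy atoms; H implied)
HBOND_ACCEPTOR_ELEMENTS = {"N", "O", "S"}
HALOGEN_ELEMENTS = {"CL", "BR", "I"}
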