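"""Package-wide physical constants and default parameters.

Units throughout the package: distances in nm, times in ns, energies in
kJ/mol, angles in degrees, temperatures in K.
"""

from __future__ import annotations

#: Boltzmann constant, kJ/mol/K.
KB = 0.0083145

#: Default simulation / analysis temperature, K.
DEFAULT_TEMPERATURE = 300.0

# ---------------------------------------------------------------------------
# Collective-variable defaults
# ---------------------------------------------------------------------------

#: Sharp native-contact scale: a contact counts as formed when the current
#: distance is below LAMBDA_CONTACT times the native distance.
LAMBDA_CONTACT = 1.2

#: Rational switching exponents (numerator, denominator) for the smooth
#: contact / coordination functions s(r) = (1 - (r/r0)^n) / (1 - (r/r0)^m).
SWITCHING_EXPONENTS = (6, 10)

#: Native-contact detection cutoff when building the reference contact set, nm.
NATIVE_CONTACT_CUTOFF = 0.45

#: Minimum nucleotide separation |i - j| for native contacts.
MIN_CONTACT_SEPARATION = 2

#: Ion-coordination switching radius r0 (K+ to guanine O6), nm.
ION_R0 = 0.35

# ---------------------------------------------------------------------------
# Metadynamics defaults.  The four hill widths follow the BEMD protocol for
# the four CVs (Q as a fraction of the 130 native contacts, dRMSD, ion
# coordination number, radius of gyration).
# ---------------------------------------------------------------------------

#: Gaussian hill height, kJ/mol.
HILL_HEIGHT = 0.2

#: Hill deposition stride tau_G, ns (toy-time).
HILL_STRIDE = 0.001

#: Hill widths per CV.  Q is stored as a fraction, so the count-scale width
#: 2.5 (out of 130 contacts) becomes 2.5/130.
CV_WIDTHS = {
    "q": 2.5 / 130.0,
    "drmsd": 0.02,   # nm
    "n_ion": 0.5,
    "rg": 0.2,       # nm
}

# ---------------------------------------------------------------------------
# Ensemble-statistics defaults
# ---------------------------------------------------------------------------

#: Donor/acceptor heavy-atom distance criterion for a hydrogen bond, nm.
HBOND_CUTOFF = 0.35

#: Donor-H-acceptor angle criterion, degrees (applied only when an explicit
#: hydrogen is present; the reduced representation carries none).
HBOND_ANGLE = 135.0

#: Ion "bound" cutoff to O6, nm (shared with the N_ion CV by default).
ION_BOUND_CUTOFF = 0.35

#: Leader-clustering dRMSD threshold, nm.
CLUSTER_THRESHOLD = 0.3

#: Looser leader-clustering threshold for high-temperature unfolding runs, nm.
UNFOLD_CLUSTER_THRESHOLD = 0.45

#: Glycosidic windows: chi in (SYN_LO, SYN_HI] degrees is syn, anti otherwise.
SYN_WINDOW = (-90.0, 90.0)

#: A nucleotide is called syn or anti outright only if that state occupies at
#: least this fraction of frames ...
FLUCTUATION_OCCUPANCY = 0.8
#: ... and fewer than this many transitions occurred; otherwise "fluctuating".
FLUCTUATION_TRANSITIONS = 2

# ---------------------------------------------------------------------------
# Free-energy-landscape defaults
# ---------------------------------------------------------------------------

#: Bins per FEL axis.
FEL_BINS = 40

#: Fractional padding added around the observed CV range.
FEL_PADDING = 0.05

#: Fraction of samples discarded as equilibration.
FEL_EQUILIBRATION = 0.2

#: Minimum number of samples for a bin to count as supported.
FEL_MIN_COUNT = 1

#: Basin merge threshold in units of k_B*T.
BASIN_MIN_BARRIER_KT = 1.0

# ---------------------------------------------------------------------------
# Atom-role mapping: PDB atom names -> internal roles.  PDB files written in
# the 1990s convention use * where modern files use ' (C4* vs C4').
# ---------------------------------------------------------------------------

DEFAULT_ROLE_MAP = {
    "C4'": "C4'",
    "C4*": "C4'",
    "O4'": "O4'",
    "O4*": "O4'",
    "C1'": "C1'",
    "C1*": "C1'",
    "N9": "N9",
    "C8": "C8",
    "O6": "O6",
    "D0": "D0",
    "D1": "D1",
    "A0": "A0",
    "A1": "A1",
    "K": "ION",
    "K+": "ION",
}

#: Roles every nucleotide of a full pseudo-atom structure carries.
CORE_ROLES = ("C4'", "O4'", "C1'", "N9", "C8", "O6")

#: Hydrogen-bond donor / acceptor pseudo-atom roles.
DONOR_ROLES = ("D0", "D1")
ACCEPTOR_ROLES = ("A0", "A1")
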