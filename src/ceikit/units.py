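"""Unit conversions between interface units (Å, eV, u, fs) and Hartree atomic units.

All physics internals run in atomic units (bohr, hartree, electron mass);
every public interface speaks Å / eV / u.  Constants are CODATA-2018 values
quoted to at least 9 significant digits.
"""

# length
ANGSTROM_TO_BOHR = 1.88972612546
BOHR_TO_ANGSTROM = 1.0 / ANGSTROM_TO_BOHR

# energy
HARTREE_TO_EV = 27.2113862460
EV_TO_HARTREE = 1.0 / HARTREE_TO_EV

# mass
AMU_TO_ME = 1822.88848622
ME_TO_AMU = 1.0 / AMU_TO_ME

# time
ATOMIC_TIME_TO_FS = 2.41888432587e-2
FS_TO_ATOMIC_TIME = 1.0 / ATOMIC_TIME_TO_FS

# velocity: 1 a.u. of velocity in Å/fs
AU_VELOCITY_TO_ANG_FS = BOHR_TO_ANGSTROM / ATOMIC_TIME_TO_FS
ANG_FS_TO_AU_VELOCITY = 1.0 / AU_VELOCITY_TO_ANG_FS

# Coulomb constant e^2/(4 pi eps0) expressed in eV·Å (unity in a.u.)
COULOMB_CONSTANT_EV_ANG = HARTREE_TO_EV * BOHR_TO_ANGSTROM  # 14.3996454...

# kinetic energy: 1 u (Å/fs)^2 in eV, i.e. (1/2) m v^2 with m in u, v in Å/fs
# gives eV after multiplying by this factor
U_ANGFS_SQ_TO_EV = AMU_TO_ME * AU_VELOCITY_TO_ANG_FS**-2 * HARTREE_TO_EV
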