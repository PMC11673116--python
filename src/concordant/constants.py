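"""Physical constants and unit conversions.

Internal unit system: lengths in Å, masses in amu, energies in aJ
(1 aJ = 1e-18 J, so stretching force constants in aJ·Å⁻² coincide with the
spectroscopist's mdyn·Å⁻¹).  GF eigenvalues λ therefore carry units of
aJ·Å⁻²·amu⁻¹ and convert to harmonic wavenumbers as ω̃ = κ·√λ.

κ is assembled from CODATA values at import; it is not hard-coded.
"""

import math

import scipy.constants as _sc

#: J per aJ
AJ = 1e-18
#: m per Å
ANGSTROM = 1e-10
#: kg per amu
AMU = _sc.atomic_mass

#: ω̃ [cm⁻¹] = WAVENUMBER_PER_SQRT_LAMBDA · sqrt(λ [aJ·Å⁻²·amu⁻¹])
WAVENUMBER_PER_SQRT_LAMBDA = math.sqrt(AJ / (ANGSTROM**2 * AMU)) / (
    2.0 * math.pi * _sc.c * 100.0
)


def eigenvalue_to_wavenumber(lam: float) -> float:
    """Convert a GF eigenvalue (aJ·Å⁻²·amu⁻¹) to cm⁻¹.

    Negative eigenvalues (imaginary modes) are returned as negative
    wavenumbers, the common spectroscopic encoding.
    """
    w = WAVENUMBER_PER_SQRT_LAMBDA * math.sqrt(abs(lam))
    return -w if lam < 0 else w
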