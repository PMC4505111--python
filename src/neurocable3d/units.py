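"""Unit conventions and conversion constants.

Internal unit system: micrometer (length), millisecond (time), millivolt
(potential), nanoampere (current).  Derived units that follow from these:

* conductivity        microsiemens / micrometer (uS/um)
* conductance density stored in mS/cm^2 (the physiological convention) and
  converted where fluxes are accumulated
* current density     microampere / cm^2 (physiological convention)
* capacitance density microfarad / cm^2

The products that actually enter the discrete equations are consistent:
``uS/um * um = uS`` and ``uS * mV = nA``; a membrane current density in
uA/cm^2 times an area in um^2 times :data:`UA_PER_CM2_TO_NA_PER_UM2` is nA.
"""

#: 1 mS/cm expressed in uS/um (0.1 S/m per mS/cm, 1 S/m = 1 uS/um).
MS_PER_CM_TO_US_PER_UM = 0.1

#: 1 uA/cm^2 expressed in nA/um^2 (1e3 nA per 1e8 um^2).
UA_PER_CM2_TO_NA_PER_UM2 = 1.0e-5


def sigma_to_internal(sigma_ms_per_cm: float) -> float:
    """Convert a conductivity from mS/cm to the internal uS/um."""
    return sigma_ms_per_cm * MS_PER_CM_TO_US_PER_UM


def current_density_to_na_per_um2(j_ua_per_cm2):
    """Convert a membrane current density from uA/cm^2 to nA/um^2."""
    return j_ua_per_cm2 * UA_PER_CM2_TO_NA_PER_UM2


def na_to_ua_per_cm2(amplitude_na: float, area_um2: float) -> float:
    """Spread a patch current (nA) over a patch area (um^2) as uA/cm^2."""
    if area_um2 <= 0.0:
        raise ValueError("patch area must be positive")
    return amplitude_na / (area_um2 * UA_PER_CM2_TO_NA_PER_UM2)
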