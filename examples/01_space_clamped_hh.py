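"""Space-clamped Hodgkin-Huxley patch: rest, threshold and spike.

Integrates the single-point membrane ODE (the 0-dimensional limit of the
cable equation) for a sub- and a suprathreshold current step and prints the
peak depolarization of each.  The suprathreshold run shows the full action
potential (~100 mV above rest, back near rest within ~15 ms); the
subthreshold one a small passive deflection.
"""

from neurocable3d import HHParameters, MembraneModel, e_l_for_rest
from neurocable3d.membrane import simulate_space_clamped

model = MembraneModel(params=e_l_for_rest(HHParameters()))

for label, density in (("subthreshold (-1 uA/cm^2)", -1.0),
                       ("suprathreshold (-15 uA/cm^2)", -15.0)):
    t, v = simulate_space_clamped(
        model, t_end=20.0, dt=0.01,
        stimulus_density=lambda tt, d=density: d if tt <= 1.0 else 0.0,
    )
    print(f"{label}: peak V_m = {v.max():6.2f} mV, final V_m = {v[-1]:+.2f} mV")

print("\nPeak ~100 mV = an action potential in the shifted convention "
      "(rest = 0 mV); the subthreshold peak stays within a few mV.")
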