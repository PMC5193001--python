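"""Predict blood concentration profiles and derived PK quantities.

Uses the published typical values for robenacoxib in cats.  The
terminal slope after SC dosing is the absorption rate (flip-flop
kinetics: ka < beta), so the SC curve decays more slowly than the IV
curve even though elimination is unchanged.
"""

import numpy as np

import saempk as sp

p = sp.IndividualParams(Ftot=0.78, F0=0.50, ka=0.68, Tk0=1.78,
                        CL=0.502, V1=0.16, Q=0.065, V2=0.047)

times = np.array([0.25, 0.5, 1, 2, 4, 8, 12])
iv = sp.conc_iv_bolus(p, 2.0, times)
scv = sp.conc_sc(p, 2.0, times)
print("time (h)   IV (ng/mL)   SC (ng/mL)")
for t, a, b in zip(times, iv, scv):
    print(f"{t:7.2f} {a:12.1f} {b:12.1f}")

ex = sp.disposition_exponents(sp.micro_constants(p))
d = sp.derived_quantities(p, bw=3.9)
print(f"\nalpha = {ex.alpha:.3f} 1/h, beta = {ex.beta:.3f} 1/h")
print(f"flip-flop (ka < beta): {d.flip_flop}")
print(f"terminal SC half-life: {d.t_half_terminal_sc:.2f} h "
      f"(absorption-limited), beta half-life: {d.t_half_beta:.2f} h")
print(f"Vss = {d.vss:.3f} L/kg; extraction ratio = "
      f"{d.extraction_ratio:.3f} (low: clearance well below cardiac "
      f"output of {d.cardiac_output:.0f} mL/kg/min)")
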