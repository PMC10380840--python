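"""Globally fit synthetic stopped-flow FRET traces of the E260A mutant.

Simulates the three-stage incision mechanism E+S <=> ES -> EP <=> E+P with
the published E260A rate constants at five enzyme concentrations
(0.25-2.0 uM over 1 uM substrate, 1% noise), then recovers the rate
constants with the association constant Ka fixed at its thermophoresis
value, as in the original global-fit protocol.
"""

from deerkin import NoiseSpec, gen_fret_traces, global_fit_scheme1
from deerkin.presets import ASSOCIATION_CONSTANTS, RATE_CONSTANTS

truth = RATE_CONSTANTS["E260A"]
ka = ASSOCIATION_CONSTANTS["E260A"]

traces = gen_fret_traces(truth, noise=NoiseSpec(sigma=0.01, seed=11))
print(f"simulated {len(traces)} traces at E0 = "
      f"{[tr.e0 for tr in traces]} uM, S0 = 1.0 uM")

params, info = global_fit_scheme1(traces, ka_fixed=ka, seed=0)
err = info["stderr"]
print(f"k1   = {params.k1:6.2f} +/- {err['k1']:.2f} 1/(uM s)   (truth {truth.k1})")
print(f"kcat = {params.kcat:6.2f} +/- {err['kcat']:.2f} 1/s        (truth {truth.kcat})")
print(f"Kp   = {params.kp:6.2f} +/- {err['kp']:.2f} uM         (truth {truth.kp})")
print("kcat ~ 4 1/s marks E260A as catalytically the slowest mutant, while its")
print("weak binding (Ka = 0.9 1/uM) further lowers overall incision efficiency.")
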