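"""Invert a synthetic DEER trace of the undamaged-DNA / zAPE1 complex.

Generates a dipolar time trace from the published bimodal distance
distribution (24%/72% at 3.94/4.60 nm, renormalised), adds noise at a
V_n signal-to-noise of 100, and runs the full inversion pipeline:
background-exponent tuning, normalisation, three-Gaussian Monte Carlo
fitting in the frequency domain and joint refinement.
"""

import numpy as np

from deerkin import BackgroundParams, NoiseSpec, gen_deer, invert_trace
from deerkin.presets import DEER_DISTRIBUTIONS

truth = DEER_DISTRIBUTIONS["undamaged-dna-complex"]
trace = gen_deer(
    truth,
    lam=0.3,
    bg=BackgroundParams(alpha=0.1, xi=1.03),
    noise=NoiseSpec.from_snr(100.0, seed=4),
)
print(f"trace: {len(trace)} points, 12 ns steps to {trace.t_us[-1]:.1f} us")

fit = invert_trace(trace, n_components=3, seed=1, snr=100.0)
print(f"background: xi = {fit.xi_best:.3f}, alpha = {fit.alpha_best:.4f} "
      f"(truth 1.03, 0.1); modulation depth = {fit.lam_best:.3f} (truth 0.3)")
for comp, artifact in zip(fit.distribution.components, fit.artifact_flags):
    note = "  <- spurious (<4%), excluded from reporting" if artifact else ""
    print(f"  component: {100 * comp.fraction:5.1f}%  r = {comp.r_mean:.2f} nm"
          f"  dr = {comp.r_sd:.2f} nm{note}")
print("The two retained peaks are the free-duplex distance (~3.94 nm) and the")
print("elongated distance in the protein complex (~4.60 nm): the enzyme")
print("unwinds the double helix, lengthening the spin-spin distance.")
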