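"""Thermophoresis binding isotherm and steady-state cleavage kinetics.

Recovers (i) the association constant Ka of the E260A-substrate complex
from a synthetic 12-point MST titration (0.1-10 uM, 1% noise) and
(ii) the observed steady-state cleavage rate constant of the wild-type
enzyme from a synthetic product-accumulation time course (2% noise).
"""

import numpy as np

from deerkin import (
    MstModelParams,
    NoiseSpec,
    ProductCurveParams,
    fit_mst_eq8,
    fit_product_eq6,
    gen_mst,
    gen_product_timecourse,
)
from deerkin.presets import ASSOCIATION_CONSTANTS, STEADY_STATE_KOBS

# --- MST isotherm, E260A ---------------------------------------------------
ka_truth = ASSOCIATION_CONSTANTS["E260A"]
truth = MstModelParams(f_backgr=100.0, f_ampl=50.0, ka=ka_truth)
conc, signal = gen_mst(truth, noise=NoiseSpec(sigma=0.01, seed=21))
fit = fit_mst_eq8(conc, signal)
print(f"E260A: Ka = {fit.ka:.2f} +/- {fit.ka_err:.2f} 1/uM (truth {ka_truth})")
print("  ~4-fold weaker binding than WT (Ka = 3 1/uM): the E260A substitution")
print("  distorts DNA binding, one reason for its low abasic-site activity.")

# --- steady-state product accumulation, WT ---------------------------------
k_obs_truth = STEADY_STATE_KOBS["WT"]
curve = ProductCurveParams(amplitude=80.0, k_obs=k_obs_truth)
t, pct = gen_product_timecourse(curve, np.linspace(2.0, 150.0, 30),
                                noise=NoiseSpec(sigma=0.02, seed=22))
fit = fit_product_eq6(t, pct)
print(f"WT:    k_obs = {fit.k_obs:.3f} +/- {fit.k_obs_err:.3f} 1/s "
      f"(truth {k_obs_truth})")
print("  Multiple-turnover cleavage of the abasic substrate; mutant k_obs")
print("  values differ by at most ~3-fold, so product release is not the")
print("  step the loop substitutions perturb most.")
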