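"""Published parameter sets for zAPE1-DNA interactions, used as generator
truths and recovery targets.

Distance-distribution parameters come from the three-Gaussian analysis of
DEER on rigid-label DNA duplexes (free and in complex with wild-type
zAPE1); rate and binding constants come from the stopped-flow /
thermophoresis analysis of the wild-type enzyme and the N253G, A254G and
E260A damage-recognition-loop mutants acting on the abasic (F-site)
substrate.

Fractions are stored renormalised to sum to one.  The bimodal
undamaged-DNA-complex distribution was published as 24%/72% with the
remainder a sub-4% spectral artifact; its two real components are kept at
their published ratio (25/75 after renormalisation).
"""

from __future__ import annotations

from .forward import DistanceDistribution
from .kinetics import Scheme1Params

__all__ = [
    "DEER_DISTRIBUTIONS",
    "RATE_CONSTANTS",
    "ASSOCIATION_CONSTANTS",
    "WT_STOPPED_FLOW_PHASES",
    "STEADY_STATE_KOBS",
]

#: Distance-distribution truths: sample name -> P(r).
DEER_DISTRIBUTIONS: dict[str, DistanceDistribution] = {
    "undamaged-dna": DistanceDistribution.from_arrays(
        [1.0], [3.94], [0.36]
    ),
    "undamaged-dna-complex": DistanceDistribution.from_arrays(
        [0.25, 0.75], [3.94, 4.60], [0.36, 0.34]
    ),
    "alpha-a-substrate": DistanceDistribution.from_arrays(
        [1.0], [4.37], [0.33]
    ),
    "alpha-a-complex": DistanceDistribution.from_arrays(
        [1.0], [4.50], [0.40]
    ),
    "f-substrate": DistanceDistribution.from_arrays(
        [0.65, 0.35], [3.45, 3.98], [0.32, 0.32]
    ),
    "f-substrate-complex": DistanceDistribution.from_arrays(
        [68.0 / 99.0, 31.0 / 99.0], [3.86, 4.51], [0.48, 0.26]
    ),
}

#: Three-stage-scheme rate constants per mutant (k1 uM^-1 s^-1, k-1 s^-1,
#: kcat s^-1, Kp uM) from the global stopped-flow fits.
RATE_CONSTANTS: dict[str, Scheme1Params] = {
    "N253G": Scheme1Params(k1=29.0, k_minus1=12.0, kcat=13.0, kp=4.0),
    "A254G": Scheme1Params(k1=24.0, k_minus1=12.0, kcat=8.0, kp=7.0),
    "E260A": Scheme1Params(k1=11.0, k_minus1=13.0, kcat=4.0, kp=10.0),
}

#: Equilibrium association constants Ka (uM^-1) from MST titrations.
ASSOCIATION_CONSTANTS: dict[str, float] = {
    "WT": 3.0,
    "N253G": 2.5,
    "A254G": 2.0,
    "E260A": 0.9,
}

#: Wild-type single-turnover FRET phases: (amplitude, rate s^-1) pairs of
#: the two-exponential fit (quench on binding, rise on incision).
WT_STOPPED_FLOW_PHASES: tuple[tuple[float, float], ...] = (
    (-0.42, 91.0),
    (1.63, 20.0),
)

#: Steady-state observed rate constants of F-substrate cleavage (s^-1).
STEADY_STATE_KOBS: dict[str, float] = {
    "N253G": 0.09,
    "WT": 0.06,
    "A254G": 0.040,
    "E260A": 0.030,
}
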