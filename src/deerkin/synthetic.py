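"""Synthetic data generators for every input kind the pipeline consumes.

No instrument data are distributed with the study this package models, so
each measurement type — DEER time traces, stopped-flow FRET sets,
steady-state product-accumulation time courses and MST titrations — is
emulated by its forward model plus additive Gaussian noise.  The defaults
reproduce the published acquisition conditions: 12 ns DEER steps over
6.5 us at a V_n signal-to-noise of 50-100, stopped-flow enzyme series
0.25-2.0 uM over 1 uM substrate, titrations 0.1-10 uM.

All generators are deterministic under a fixed seed.  Noise conventions:

* DEER — the signal-to-noise ratio refers to the *normalised* dipolar
  trace V_n(t), so the raw-trace noise is scaled by the modulation
  amplitude ``lambda * V(0) * V_inter(t)``; after background removal and
  normalisation the noise on V_n is white with std 1/SNR.
* stopped-flow — ``sigma`` is a fraction of the noiseless trace's
  peak-to-peak amplitude (default 1%).
* product accumulation — ``sigma`` is a fraction of the burst amplitude;
  outputs are clipped to [0, 100] %.
* MST — ``sigma`` is a fraction of the isotherm amplitude ``F_ampl``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidInputError
from .forward import (
    BackgroundParams,
    DeerTrace,
    DistanceDistribution,
    GaussianComponent,
    compose_trace,
    default_time_grid,
    inter_signal,
)
from .kinetics import (
    EP_KOFF_DEFAULT,
    FretTrace,
    MstModelParams,
    ObservableCoefficients,
    ProductCurveParams,
    Scheme1Params,
    fret_observable,
    simulate_scheme1,
)

__all__ = [
    "NoiseSpec",
    "gen_deer",
    "gen_fret_traces",
    "gen_product_timecourse",
    "gen_mst",
    "DEFAULT_E0_LIST_UM",
    "DEFAULT_MST_GRID_UM",
]

#: Stopped-flow enzyme concentration series (uM) over 1.0 uM substrate.
DEFAULT_E0_LIST_UM = (0.25, 0.5, 1.0, 1.5, 2.0)

#: MST titration grid: 12 log-spaced enzyme concentrations, 0.1-10 uM.
DEFAULT_MST_GRID_UM = np.geomspace(0.1, 10.0, 12)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise: relative std ``sigma`` and RNG ``seed``.

    ``sigma`` is interpreted in the units of each generator's normalised
    signal amplitude (see module docstring); ``NoiseSpec.from_snr(s)``
    gives ``sigma = 1/s``.
    """

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidInputError("noise sigma must be >= 0")

    @classmethod
    def from_snr(cls, snr: float, seed: int = 0) -> "NoiseSpec":
        if snr <= 0:
            raise InvalidInputError("SNR must be positive")
        return cls(sigma=1.0 / snr, seed=seed)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_deer(
    truth: DistanceDistribution,
    lam: float = 0.3,
    bg: BackgroundParams = BackgroundParams(alpha=0.1, xi=1.03),
    noise: NoiseSpec | None = None,
    t_grid=None,
    v0: float = 1.0,
    artifact_fraction: float | None = None,
    artifact_r_nm: float = 2.7,
    artifact_sd_nm: float = 0.1,
) -> DeerTrace:
    """Forward-simulate a DEER trace, optionally with the 2H-modulation
    artifact emulated as an extra sub-4% Gaussian at 2.6-2.8 nm.

    Noise is additive Gaussian with std ``noise.sigma`` in units of the
    normalised trace, i.e. raw std ``noise.sigma * lam * v0 * V_inter(t)``
    (falling back to ``noise.sigma * v0`` for an unmodulated trace).
    """
    if artifact_fraction is not None:
        if not 0.0 < artifact_fraction < 0.04:
            raise InvalidInputError("artifact fraction must lie in (0, 0.04)")
        if not 2.6 <= artifact_r_nm <= 2.8:
            raise InvalidInputError("artifact position must lie in [2.6, 2.8] nm")
        comps = tuple(
            replace(c, fraction=c.fraction * (1.0 - artifact_fraction))
            for c in truth.components
        ) + (GaussianComponent(artifact_fraction, artifact_r_nm, artifact_sd_nm),)
        truth = replace(truth, components=comps)
    if t_grid is None:
        t_grid = default_time_grid()
    trace = compose_trace(truth, lam, bg, v0, t_grid, method="fresnel")
    if noise is None or noise.sigma == 0:
        return trace
    scale = lam * v0 if lam > 0 else v0
    sigma_t = noise.sigma * scale * inter_signal(bg, trace.t_us)
    sig = trace.signal + noise.rng().normal(0.0, 1.0, trace.t_us.size) * sigma_t
    return replace(trace, signal=sig, noise_sigma=noise.sigma)


def gen_fret_traces(
    params: Scheme1Params,
    coefficients: ObservableCoefficients | None = None,
    e0_list=DEFAULT_E0_LIST_UM,
    s0: float = 1.0,
    noise: NoiseSpec | None = None,
    t_grid=None,
    offset: float = 0.1,
    ep_koff: float = EP_KOFF_DEFAULT,
    drift_per_s: float = 0.0,
) -> list[FretTrace]:
    """Simulate a stopped-flow series at several enzyme concentrations.

    Noise std per trace is ``noise.sigma`` times that trace's noiseless
    peak-to-peak amplitude (default protocol: 1%).  ``drift_per_s`` adds
    an optional linear signal drift emulating photobleaching of the
    fluorophore on slow time scales (off by default).
    """
    if len(e0_list) == 0:
        raise InvalidInputError("e0_list must be non-empty")
    if coefficients is None:
        coefficients = ObservableCoefficients()
    if t_grid is None:
        t_grid = np.geomspace(1e-3, 200.0, 250)
    rng = noise.rng() if noise is not None else None
    out = []
    for e0 in e0_list:
        traj = simulate_scheme1(params, e0, s0, t_grid, ep_koff=ep_koff)
        tr = fret_observable(traj, coefficients, offset)
        if drift_per_s:
            tr = replace(tr, signal=tr.signal + drift_per_s * tr.time_s)
        if rng is not None and noise.sigma > 0:
            amp = float(tr.signal.max() - tr.signal.min())
            sig = tr.signal + rng.normal(0.0, noise.sigma * max(amp, 1e-12),
                                         tr.signal.size)
            tr = replace(tr, signal=sig)
        out.append(tr)
    return out


def gen_product_timecourse(
    params: ProductCurveParams,
    t_points,
    noise: NoiseSpec | None = None,
):
    """Steady-state product accumulation, percent product vs time.

    Returns ``(t_s, product_pct)``; noisy values are clipped to [0, 100] %.
    """
    t = np.asarray(t_points, dtype=float)
    y = params(t)
    if noise is not None and noise.sigma > 0:
        y = y + noise.rng().normal(
            0.0, noise.sigma * max(params.amplitude, 1e-12), t.size
        )
    return t, np.clip(y, 0.0, 100.0)


def gen_mst(
    params: MstModelParams,
    conc_grid=None,
    noise: NoiseSpec | None = None,
):
    """MST titration points ``(conc_uM, signal)`` on a log-spaced grid."""
    c = np.asarray(
        DEFAULT_MST_GRID_UM if conc_grid is None else conc_grid, dtype=float
    )
    y = params(c)
    if noise is not None and noise.sigma > 0:
        y = y + noise.rng().normal(
            0.0, noise.sigma * max(abs(params.f_ampl), 1e-12), c.size
        )
    return c, y
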