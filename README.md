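# deerkin

Quantitative analysis of AP endonuclease–DNA interactions from two kinds of
biophysical measurement:

1. **DEER/PELDOR dipolar spectroscopy** on doubly spin-labelled DNA
   duplexes — forward simulation of dipolar time traces and their
   inversion to spin–spin distance distributions, used to detect
   enzyme-induced unwinding of the double helix;
2. **Pre-steady-state enzyme kinetics** of abasic-site incision by zAPE1
   (zebrafish APE1) and its damage-recognition-loop mutants N253G, A254G
   and E260A — mass-action simulation and global fitting of stopped-flow
   FRET traces, exponential phase analysis, steady-state product
   accumulation and thermophoresis binding isotherms.

No instrument data accompany the study this package models, so a
first-class synthetic-data module regenerates every measurement type from
its published truth parameters; all benchmarks are parameter-recovery
experiments on that synthetic data.

## Models

**DEER.** The echo amplitude of a doubly labelled molecule is

```
V(t) = V(0) · V_inter(t) · V_intra(t)
V_inter(t) = exp(−α t^ξ)                      (excluded-volume background)
V_intra(t) = 1 − λ ⟨cos(D r⁻³ (1 − 3cos²θ) t)⟩
```

with modulation depth λ, dipolar constant D (D/2π ≈ 52.2 MHz·nm³ for a
nitroxide pair) and powder averaging over the inter-spin angle θ and the
distance distribution P(r), modelled as a mixture of up to three
Gaussians.  Inversion: background-exponent tuning by minimising the
zero-frequency artifact of the cosine-Fourier spectrum, normalisation to
`V_n(t) = ⟨cos⟩`, Monte Carlo multi-Gaussian fitting in the frequency
domain (2×10⁵ draws + local polish), joint time-domain refinement, and
Δχ²=1 scanning for dispersion uncertainties.  Components below 4%
fraction or in the 2.6–2.8 nm residual-deuterium-modulation window are
flagged as artifacts.

**Kinetics.** The minimal incision mechanism is

```
E + S ⇌(k1, k−1) ES →(kcat) EP ⇌(Kp) E + P
```

fit globally across enzyme concentrations with the association constant
Ka = k1/k−1 fixed from thermophoresis.  Individual curves are fit with
exponential polynomials `F(t) = Σ Aₙ e^(−kₙ t)`; steady-state cleavage
with `[P](t) = A(1 − e^(−k_obs t)) + k_lin t`; binding isotherms with
`F = F_backgr + F_ampl·[E]/(1/Ka + [E])`.

## Worked example

```python
from deerkin import BackgroundParams, NoiseSpec, gen_deer, invert_trace
from deerkin.presets import DEER_DISTRIBUTIONS

truth = DEER_DISTRIBUTIONS["undamaged-dna-complex"]   # 25%/3.94 nm + 75%/4.60 nm
trace = gen_deer(truth, lam=0.3, bg=BackgroundParams(alpha=0.1, xi=1.03),
                 noise=NoiseSpec.from_snr(100.0, seed=4))
fit = invert_trace(trace, n_components=3, seed=1, snr=100.0)
for comp, artifact in zip(fit.distribution.components, fit.artifact_flags):
    print(f"{100*comp.fraction:5.1f}%  r = {comp.r_mean:.2f} nm  "
          f"dr = {comp.r_sd:.2f} nm  artifact={artifact}")
```

prints

```
 74.5%  r = 4.60 nm  dr = 0.33 nm  artifact=False
 23.9%  r = 3.91 nm  dr = 0.33 nm  artifact=False
  1.6%  r = 6.00 nm  dr = 1.00 nm  artifact=True
```

— the two retained peaks are the free-duplex distance (~3.94 nm) and the
elongated distance in the protein complex (~4.60 nm, DNA unwinding by the
bound enzyme), and the sub-4% third Gaussian is flagged as spurious.
(The split between strongly overlapping components wanders between
statistically equivalent solutions from one noise realisation to the
next — see `docs/methods.md` — which is why the recovery benchmarks
report replicate medians.)  The
scripts in `examples/` walk through each capability the same way
(`python examples/deer_inversion.py`, `examples/kinetics_global_fit.py`,
`examples/exponential_phases.py`, `examples/binding_and_steady_state.py`).

A thin CLI mirrors the library:

```bash
deerkin reproduce undamaged-dna-complex --out out/ --seed 1
deerkin deer-fit out/trace.csv --components 3 --snr 100 --out fit.json
deerkin kin-globalfit traces/ --ka 0.9 --out fit.json
```

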