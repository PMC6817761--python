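# methylrelax

Quantitative modelling of **¹³C spin–lattice (T₁) relaxation of methyl groups
in rotating solids**, for solid-state NMR spectroscopists extracting side-chain
dynamics from variable-temperature saturation-recovery data on isotopically
enriched samples.

In a crystalline powder under magic-angle spinning (MAS), methyl ¹³C
relaxation is driven by the C–H dipolar couplings modulated by rotation of the
methyl group about its C₃ axis.  Three complications make a naive
T₁-to-correlation-time analysis fail:

1. **Powder anisotropy** — the rate depends on the orientation of the C₃ axis,
2. **Coupled recovery** — the methyl ¹H and ¹³C magnetizations relax as a
   coupled (Solomon) system, so recovery is intrinsically multi-exponential,
3. **¹³C–¹³C spin diffusion** — in uniformly ¹³C-enriched samples the slowly
   relaxing backbone carbons act as a polarization sink, retarding the final
   stage of the methyl recovery and contaminating the slow rate.

`methylrelax` implements the full forward model and its inversion.

## The model

**Transition rates.**  For free diffusion of the C–H vector on a cone of
half-angle Θ about the C₃ axis, the dipolar transition probabilities are
linear combinations of Lorentzian spectral densities
g(τ, ω) = τ/(1 + ω²τ²) at the zero-, single- and double-quantum frequencies,
with two correlation times τ₁ and τ₂ = τ₁/4 (first and second rotational
harmonic).  Under MAS the orientation factors become time-dependent through
cos θ(t) = √(2/3) sin β cos(ω_r t + φ) + √(1/3) cos β; averaging over the rotor
period and then over the powder (justified because relaxation per rotor period
is ~10⁻⁴) yields closed forms, e.g.

    W₀  = (3ω_D²/40)  [g(τ₁, ω_I−ω_S) sin²2Θ + g(τ₂, ω_I−ω_S) sin⁴Θ]
    W₁S = (9ω_D²/80)  [g(τ₁, ω_S)    sin²2Θ + g(τ₂, ω_S)    sin⁴Θ]
    W₂  = (18ω_D²/40) [g(τ₁, ω_I+ω_S) sin²2Θ + g(τ₂, ω_I+ω_S) sin⁴Θ]

with ω_D = (μ₀/4π)γ_Iγ_Sħ/r³ and every squared coupling scaled once by a
librational order parameter S².

**Recovery.**  The deviations m = M_z(t) − M_z(∞) of the proton (I), methyl
carbon (S) and bath carbon (B) populations obey dm/dt = −R m with

    R = [[R_II,  R_IS,        0   ],
         [R_SI,  R_SS + n_Bσ, −σ  ],
         [0,     −n_Bσ,        σ  ]]

where the 2×2 I/S block is the Solomon matrix built from the W's, n_B is the
effective number of enriched bath carbons and σ the spin-diffusion
cross-relaxation rate.  Saturation recovery of the carbons gives

    M(t) = M₀ (1 − α₁e^{−λ'₁t} − α₂e^{−λ'₂t} − α₃e^{−λ'₃t}),   Σα_k = 1,

effectively bi-exponential because one amplitude is negligible (|α₃| ≲ 0.02).

**Temperature dependence.**  τ₁(T) = τ₀ exp(E_a/RT).  Fitting τ₁ per
temperature (bath parameters fixed) and regressing ln τ₁ on 1/T yields the
activation energy of methyl rotation.

## Worked example

```python
import numpy as np
from methylrelax import (ArrheniusParams, FieldConditions, MethylGeometry,
                         RecoveryModel, generate_temperature_series,
                         predict_alpha_curve)

geom  = MethylGeometry(theta_is_deg=69.1, r_is=1.106, s2=0.93)
field = FieldConditions.from_proton_mhz(800.0, mas_khz=19.2)
arr   = ArrheniusParams(ea=3.5, tau0=2.5e-13)   # kcal/mol, s

# forward model: fast/slow rates and fast amplitude vs temperature
print(predict_alpha_curve(geom, field, arr, n_b=1.6, sigma=0.9).to_string(index=False))
```

```
 temperature_K       tau1_s  lambda_fast  lambda_slow    alpha
         268.0 1.786836e-10     5.284588     0.569809 0.590928
         233.0 4.795334e-10     7.320476     0.683899 0.731137
         198.0 1.824424e-09     7.966454     0.712960 0.772236
         178.0 4.956687e-09     6.363734     0.656154 0.710606
         149.0 3.400708e-08     2.953073     0.269316 0.229200
```

The fast eigenvalue (s⁻¹) tracks the intra-methyl relaxation through its T₁
minimum near 1/ω_C; the slow one is dominated by spin diffusion to the bath;
`alpha` is the fraction of the recovery carried by the fast process — it
collapses at low temperature as the bath drains the methyl polarization.

```python
# inverse problem on synthetic data with 1% noise
data = generate_temperature_series(geom, field, arr, n_b=1.6, sigma=0.9,
                                   noise_sigma=0.01, seed=7)
res = RecoveryModel(data, geom, field).fit(method="tau1", n_b=1.6, sigma=0.9)
print(res.arrhenius().summary())
```

```
Arrhenius regression of ln(tau1) on 1/T
============================================================
parameter                    value            stderr
E_a (kcal/mol)                3.47              0.12
tau_0 (s)                2.827e-13           8.9e-14
============================================================
```

The generating E_a = 3.5 kcal/mol and τ₀ = 2.5×10⁻¹³ s are recovered within
one standard error.  A command-line interface mirrors these pipelines
(`methylrelax predict | simulate | fit | gridsearch | arrhenius |
validate-averaging`).

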