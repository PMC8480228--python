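# Methods

## Model structure

`herdclim` emulates global-mean warming from two emission components — net
CO2 (Gt CO2/yr, may be negative) and livestock CH4 (Mt CH4/yr) — with the
linear response-function chain common to reduced-complexity climate models:

1. **CO2 cycle.** The airborne fraction of an emitted pulse follows
   `IRF(t) = a0 + Σ_{i=1..3} a_i e^(−t/τ_i)` with a permanently airborne
   fraction `a0`. Defaults (`a0 = 0.2173`, `a = (0.2240, 0.2824, 0.2763)`,
   `τ = (394.4, 36.54, 4.304)` yr) are the multi-model-mean impulse-response
   fit widely used for emission metrics; 7.814 Gt CO2 per ppm converts mass
   to mixing ratio. The fractions must sum to 1, so a fresh pulse is exactly
   conserved. State-dependent carbon-cycle feedbacks are out of scope.
2. **CH4 box.** A single well-mixed box with perturbation lifetime
   `τ = 12` yr (configurable 11.8–12.4) and 2.75 Mt CH4 per ppb:
   `dC/dt = E/m − C/τ`. Chemistry feedbacks on the lifetime are not
   modelled.
3. **Forcing.** CH4: direct radiative efficiency 3.63·10⁻⁴ W/m² per ppb
   multiplied by 1.65 for indirect effects (tropospheric ozone,
   stratospheric water vapour). CO2: by default *linearized* at
   0.0134 W/m² per ppm (≈ 5.35/400), which makes the whole chain linear in
   emissions so that warming decomposes exactly; a logarithmic mode
   (`5.35 ln(1 + ΔC/400)`) is available and changes bundled-scenario results
   by less than 0.002 °C.
4. **Thermal response.** Two-mode energy balance
   `R(t) = Σ_j (q_j/d_j) e^(−t/d_j)`, response times `d = (8.4, 409.5)` yr.
   The mode structure and time constants follow the AR5 metric convention,
   but the amplitudes are scaled to `q = (0.483, 0.328)` K/(W/m²) so that
   equilibrium climate sensitivity is 3.0 K per CO2 doubling
   (Σq · 3.7 W/m² = 3.0 K) — the median of the probabilistic MAGICC-style
   ensembles this emulator stands in for. The unscaled convention
   (q = (0.631, 0.429), ECS 3.9 K) runs every temperature diagnostic about
   25 % hot relative to published median results and is available through
   configuration. With the defaults the emulator's emergent properties are
   GWP100(CH4) = 29.1 and TCRE ≈ 0.51 K per 1000 Gt CO2.

### Discretization

Emissions and forcing are piecewise-constant over calendar years;
exponential kernels are integrated analytically (lag-k response
`τ(1 − e^(−1/τ}) e^(−k/τ)`), and anomalies are reported at year-end. The
solver is therefore *exact* for piecewise-constant inputs: refining the
internal time step changes nothing, and the standard closed forms (steady
state `Eτ/m`, step-forcing transient `Σ q_j (1 − e^(−t/d_j))`) hold to
machine precision. A single-year pulse behaves like a continuous mid-year
pulse to O(1/τ²) (0.03 % for CH4).

## Synthetic scenarios

The paper-scale inputs (an SR15 scenario-database average and GLEAM 2010
emissions) are not bundled; deterministic generators reproduce their
printed shape facts instead:

- **1.5 °C-consistent CO2**: 35 Gt/yr in 2020 (a calibration choice for the
  2020 global net total), geometric 4.9 %/yr decline 2020–2030, monotone
  shape-preserving (PCHIP) descent to net-zero in 2055, net-negative to
  −10 Gt/yr in 2100 (anchor −9 at 2080). The free mid-anchor between 2030
  and 2055 is root-found so the trapezoidal cumulative total 2018→net-zero
  is exactly 580 Gt. Pre-2020 emissions grow at 1 %/yr (stylized).
- **1.5 °C-consistent livestock CH4**: 2010 level 70/0.62 = 112.9 Mt/yr so
  that 2050 = 70 Mt/yr is a 38 % drop; PCHIP decline to 55 Mt/yr in 2100
  (the post-2050 "declines further" level is not printed; 55 is a
  configurable choice). Before 2020 it follows the BAU growth trend, so BAU
  and mitigation agree exactly through 2020.
- **BAU livestock CH4**: geometric growth 2010→2050 to 1.3× the 2010 level
  (146.8 Mt/yr), held constant after 2050 (projections end at 2050; a
  linear-continuation alternative is configurable).
- **Historical backdrop** (1850–2020): exponential ramps joining the
  scenario's modern segment (CO2 from 0.2 Gt/yr, livestock CH4 from
  30 Mt/yr in 1850). This is a deliberately stylized fixture used only for
  legacy-warming displays; marginal quantities never depend on it, and
  attribution results carry a flag to that effect.

What the generators do *not* emulate: multi-gas interactions (N2O,
aerosols), regional disaggregation, interannual variability, or the spread
across integrated-assessment models. Tests passing on these scenarios show
the method's arithmetic and its calibrated magnitudes are right, not that
any particular real-world scenario database would give identical numbers.

## Attribution

Marginal warming of a pathway after a split year (default 2020, zeroing
from 2021) is warming(full) − warming(zeroed-after-split); in linearized
mode this equals the warming of the future emissions alone and
total = legacy + marginal holds to machine precision. Report years default
to 2050 and 2100. The historical livestock share of warming is the plain
product of two assessed fractions (CH4's share of anthropogenic forcing ×
livestock's share of anthropogenic CH4), reported in percent.

## Budget inversion

The trade-off question — how much net CO2 room does unmitigated livestock
CH4 consume? — is answered by adjusting the reference CO2 pathway until
combined warming with the warmer CH4 alternative matches the reference
case. The adjusted-pathway family has two parameters:

- `s`: scales the reference decline increments over 2020–2035 (steeper
  near-term cuts, earlier net-zero);
- `u`: the offset from the reference trajectory after 2035 decays back to
  the pinned 2100 floor as `((2100 − t)/65)^u`, so small `u` keeps the
  extra CO2 removal deep for longer ("more and earlier removal").

Nested bracketed root-finds (Brent, brackets s ∈ [0.5, 3], u ∈ [0.05, 3],
xtol 10⁻⁴) zero the warming difference at 2050 and 2100; success requires
the maximum absolute difference over 2020–2100 to stay below 0.01 °C
("virtually identical" made precise). A one-parameter variant (scale +
proportional rejoin) was tried first and cannot do better than 0.023 °C on
the bundled scenarios — it front-loads cooling while the CH4 warming
difference keeps growing to 2100 — which is why the family has two
parameters. Matching the full trajectory rather than only peak warming is
a design choice; matching at the peak alone would loosen the late-century
constraint and shrink the budget delta somewhat.

Budget arithmetic: net-zero year by linear interpolation at the first
downward zero-crossing ("never" is an explicit result, not an exception);
cumulative emissions by trapezoid from the 2018 start year to the
(fractional) net-zero year; reduction rates as geometric means.

## CH4 stabilization rate

The decline rate that stabilizes CH4-induced warming is found by bisection
on r such that warming at the end of a 50-year window equals warming at its
start, after a 60-year constant-emission spin-up. The spin-up length is
five CH4 lifetimes: long enough that the concentration is within 1 % of
steady state (shorter spin-ups leave a gas-cycle transient that
contaminates the result), short enough that the slow thermal mode is still
far from equilibrium — mimicking the present-day situation in which CH4
concentrations have roughly plateaued while deep-ocean warming continues.
With defaults the answer is 0.28 %/yr; it grows with shorter spin-up and
shrinks with longer, so it should be read as "a few tenths of a percent per
year", not a constant of nature.

## Mitigation potentials

Potential = Σ over applicable (system × income-group) rows of
2010 emissions × growth (default 1.3 to 2050) × efficacy × adoption.
The bundled emissions table is *synthetic*: the true system-by-income
disaggregation is not public in the sources used here, so the feedlot total
is back-calibrated to make the canonical TMR-inhibitor case (30 % efficacy,
full adoption) equal 0.8 Mt CH4/yr, and the other cells are plausible
invented values summing to ~100 Mt/yr. Potentials computed from it are
illustrative; supply a real GLEAM extract (CSV with columns
`system, income_group, mt_ch4_2010`) for quantitative use. A potential can
be coupled into a pathway as an abatement wedge ramping linearly from 2025
(configurable) to full size in 2050 and held thereafter, clipped at zero.

## Numerical and interface notes

- Everything is deterministic; there is no random number generator anywhere
  in the package, and identical configurations produce byte-identical
  CSV/JSON outputs.
- Degenerate inputs: single-anchor scenarios hold constant; pathways that
  never cross zero report net-zero as "never"; a zero-mass pulse has zero
  metrics; identical reference and alternative CH4 pathways short-circuit
  the inversion to the identity.
- Problem sizes: bundled scenarios span 2000–2100 (101 years), the
  stabilization run 111 years, and closed-form asymptote checks use a few
  thousand years; every analysis completes in well under a minute.
- Known limitations: no carbon-cycle or lifetime feedbacks, single
  deterministic trajectory (no probabilistic ensemble), two gases only, and
  the legacy/stabilization results inherit the stylized spin-up/backdrop
  assumptions described above.
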