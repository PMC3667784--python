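# invadosim

Kinetic and reaction–diffusion simulation of MT1-MMP activity and ECM
degradation at invadopodia.

Invasive cancer cells degrade the extracellular matrix (ECM) at
invadopodia, membrane protrusions where the transmembrane collagenase
MT1-MMP is delivered by rapid vesicular trafficking. MT1-MMP is inhibited
by soluble TIMP-2 within seconds of reaching the surface, yet TIMP-2 also
serves as the adaptor that lets MT1-MMP activate pro-MMP-2. `invadosim` is
a simulator for this protease–inhibitor network, built for exploring why
the *brief* burst of activity that follows each insertion — not the
long-lived steady state — carries most of the degradation.

The package provides, as composable library modules:

* **`network`** — enumeration of every MT1-MMP/TIMP-2/MMP-2 complex
  (monomers, dimers through the hemopexin domain, ECM-engaged and
  shed-fragment forms) and the mass-action reaction list, with
  path-deletion and ectodomain-shedding variants and a reviewable
  reaction-table export;
* **`kinetics`** — compiled mass-action ODEs integrated with a fixed-step
  4th-order Runge–Kutta scheme (numba), with event hooks for vesicle
  pulses and explicit steady-state detection;
* **`turnover`** — continuous and pulsatile MT1-MMP delivery through the
  two invadopodial docking pools (time constants 259 s and 26.0 s),
  regular/random schedules, and the transient-elimination insertion mode;
* **`ecm`** — explicit enzyme–substrate degradation kinetics and the
  metrics τ_H (time to half ECM) and initial degradation rate;
* **`spatial`** — a 51×51×1-compartment reaction–diffusion model of focal
  degradation at a ~0.9 µm invadopodium with diffusing TIMP-2/MMP-2;
* **`experiments`** — M14a activity metrics, TIMP-2 titrations, τ_H
  ensembles, and presets for the standard in-silico experiments, plus an
  `invadosim` command-line interface.

The central observable is the ECM-degradation-competent activity

    M14a = [M14] + 2[M14.M14] + [M14.M14.T2] + [M14.M14.T2.M2]

and its derived metrics: the plateau `M14a_steady`, the transient
half-width `t_transient`, and τ_H.

## Worked example

```python
import invadosim as iv
from invadosim.experiments import (run_core, m14a_weights, transient_metrics,
                                   run_to_half_ecm)

# 100 nM MT1-MMP expressed at t=0 against 100 nM TIMP-2 and pro-MMP-2
traj = run_core(timp2=100.0)
net = iv.build_core_network(pools="single")
m = transient_metrics(traj, m14a_weights(net))
print(f"peak {m.peak_value:.1f} nM, half-width {m.t_transient:.2f} s, "
      f"steady {m.M14a_steady:.2f} nM")

# cost of removing the insertion transient at high TIMP-2
tau_p, _, _ = run_to_half_ecm(timp2=500.0)
tau_e, _, _ = run_to_half_ecm(timp2=500.0, eliminate_transient=True,
                              t_start_horizon=64 * tau_p)
print(f"tau_H present {tau_p:.0f} s, eliminated {tau_e:.0f} s "
      f"(ratio {tau_e / tau_p:.0f}x)")
```

prints

```
peak 100.0 nM, half-width 2.97 s, steady 10.32 nM
tau_H present 409 s, eliminated 70246 s (ratio 172x)
```

Read: the freshly expressed enzyme is quenched by TIMP-2 within about
three seconds, leaving a ~10% steady activity; and at 500 nM TIMP-2,
forcing newly inserted enzyme to arrive pre-distributed across its
steady-state complexes (no transient) slows ECM half-degradation by more
than two orders of magnitude — the transient does the work.

From the shell:

```
invadosim sweep --timp2 0:500:100                 # TIMP-2 titration
invadosim run --preset fig4 --out out/ --seed 1   # preset experiment bundle
invadosim network --export reactions.tsv          # audit the reaction list
```

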