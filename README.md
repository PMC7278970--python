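# dsbsurv

Mechanistic modelling of clonogenic cell survival after photon irradiation,
with an explicit split of DNA double-strand-break (DSB) induction into
direct and indirect (radical-mediated) action. The package predicts
surviving fractions under normoxia and hypoxia, with and without the
radical scavenger DMSO, and reproduces the full parameter-fitting workflow
from survival tables. It is aimed at computational radiobiologists who
want a small, testable implementation of the giant-loop survival model to
fit their own clonogenic data or to generate synthetic dose–response
tables with known ground truth.

## The model

Photon dose deposits homogeneously over a nucleus of DNA content
DNA_c = 6000 Mbp, inducing DSBs at a cell-line-independent rate
α_DSB = 5×10⁻³ DSB/(Mbp·Gy), so the expected total yield at dose D is

    ⟨N_tDSB⟩ = α_DSB · D · DNA_c

The genome is tiled into N_gl = DNA_c / DNA_gl = 3000 giant loops of
DNA_gl = 2 Mbp, the critical targets. The sampled total break count
(Poisson) is distributed uniformly over the loops; a loop with exactly one
break is an isolated lesion (iDSB), with two or more a complex lesion
(cDSB). Each lesion independently inactivates the cell, giving

    S = (1 − K_iDSB)^N_iDSB · (1 − K_cDSB)^N_cDSB

and the population surviving fraction is the mean of S over realizations.
Because per-loop counts are i.i.d. Poisson(μ = ⟨N⟩/N_gl), that mean has the
closed form

    E[S] = [e^−μ + (1−K_i)·μe^−μ + (1−K_c)·(1 − e^−μ − μe^−μ)]^N_gl

which the package uses as a deterministic predictor for fitting and as an
exact oracle for the Monte Carlo path.

A fraction fr_DIR = 20% of the yield is due to direct energy deposition on
DNA; only the remaining indirect, OH-radical-mediated fraction responds to
chemistry. DMSO at concentration c (molar) scales the indirect yield by
f_DMSO = exp(−a·c^b) with a = 0.9065, b = 0.4172. Hypoxia divides the
total yield by a hypoxia reduction factor HRF (the DSB-level analogue of
the oxygen enhancement ratio), parametrized in oxygen concentration as
HRF([O₂]) = (m·K + [O₂])/(K + [O₂]) with m = 2.94 and K = 0.129%; the
direct term is oxygen-independent, so under hypoxia

    ⟨N_tDSB,O₂⟩ = fr_DIR·α·D·DNA_c + (α/HRF − α·fr_DIR)·D·DNA_c·f_DMSO

Fitted per-cell-line parameters for CHO, AA8 and V79 ship as a registry.

## Worked example

```python
import dsbsurv as d

nuc = d.NucleusModel()                 # alpha=5e-3, 6000 Mbp, 2 Mbp loops
cho = d.get_cell_line("CHO")           # fitted K_iDSB, K_cDSB, HRF

# expected DSB yields at 4 Gy, 0.5 M DMSO
y_norm = d.expected_dsb_normoxic(nuc, 4.0, 0.5)
y_hyp = d.expected_dsb_hypoxic(nuc, 4.0, 0.5, cho.hrf)
print(round(y_norm, 2), round(y_hyp, 2))
# 72.69 32.81

# surviving fractions (closed form and Monte Carlo)
s = d.analytic_mean_survival(y_norm, d.n_loops(nuc), cho.lethality)
est = d.mc_mean_survival(y_norm, d.n_loops(nuc), cho.lethality,
                         n_samples=100_000, seed=1)
print(round(s, 4), round(est.mean, 4))
# 0.3473 0.3483
```

At 4 Gy, 0.5 M DMSO roughly halves the scavengeable indirect yield
(f_DMSO ≈ 0.507), dropping the expected break count from 120 to ≈72.7
under normoxia; hypoxia (HRF = 2.90) reduces it further to ≈32.8. The
Monte Carlo estimate agrees with the closed-form mean to within its
standard error.

The same machinery is available from the shell:

    dsbsurv rdsb-curve --max 3.0 --steps 4
    dsbsurv simulate --cell-line CHO --noise 0.05 --output sim.csv
    dsbsurv fit-lethality --input sim.csv
    dsbsurv predict --input sim.csv

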