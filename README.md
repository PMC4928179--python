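# saxsflex

Structure-free quantification of protein conformational flexibility from
small-angle X-ray scattering (SAXS) data.

A protein in solution samples an ensemble of conformations; SAXS measures the
ensemble-averaged intensity I(q).  Methods that reconstruct explicit
structural ensembles from I(q) are badly under-determined — many different
ensembles fit the same curve.  `saxsflex` instead reduces every conformation
to its radius of gyration Rg, models the single-conformation intensity as
that of a homogeneous sphere, I_S(q, Rg), and fits a log-normal density
P_{μ,σ}(Rg) so that

    I_{μ,σ}(q) = ∫₀^∞ P_{μ,σ}(Rg) · I_S(q, Rg) dRg

matches the measured low-q decade.  The flexibility measure is the
differential entropy of the fitted size distribution,

    S = μ̂ + 1/2 + ln(σ̂·√2π)   [nats],

a single continuous number: compact folded proteins sit low on the scale
(S ≲ 3.4), intrinsically disordered proteins high (S ≳ 4.3), and
ligand-induced rigidification or loosening shows up as a shift in S — all
without building a single structural model.  The package also provides the
classical diagnostics used alongside such an analysis: Guinier fitting,
Kratky and dimensionless Kratky plots (ideal compact particles peak at
(√3, 3e⁻¹ ≈ 1.104)), Porod and Porod-Debye transforms with heuristic plateau
detection, and an entropy-quartile flexibility classification
(cut-points 3.37 / 3.86 / 4.26 nats).

For whom: structural biologists and beamline users with 3-column `.dat`
profiles (BIOISIS / SASBDB / ATSAS dialect) who want a quantitative,
structure-free flexibility readout; and method developers who need a
seeded synthetic-profile generator with ground truth attached.

## Worked example

Generate the bundled synthetic triple (folded / partially disordered / IDP,
1% noise) and fit the disordered member:

```
$ saxsflex simulate --out fixtures --seed 7
fixtures/folded.dat
fixtures/partial.dat
fixtures/disordered.dat

$ saxsflex fit fixtures/disordered.dat --resamples 50 --out disordered.fit.json
disordered:
  mu_hat    = 3.604387  (median Rg 36.76 A)
  sigma_hat = 0.604983
  entropy S = 4.5208 nats +/- 0.0087
  class     = Q4_disordered
  misfit    = 9.375e-05  q-window = [0.0050, 0.0984] 1/A
```

Reading: the fitted log-normal has median Rg e^3.604 ≈ 36.8 Å and log-width
σ̂ ≈ 0.60 — a broad size distribution.  Its entropy S = 4.52 nats lands in
the top quartile (`Q4_disordered`) of the flexibility scale, as it should
for this IDP-like fixture (true generating values: μ = 3.6, σ = 0.60,
S = 4.51).  The ±0.0087 is the standard deviation of S over 50 refits with
the profile's reported errors resampled — noise at the 1% level moves S by
only ~0.2%, so the quartile call is robust.  The q-window shows the fit used
the low-q decade (I down to I(0)/10), where the sphere reduction is valid.

Classical diagnostics for the folded member:

```
$ saxsflex diagnose fixtures/folded.dat --out diag
Guinier: Rg = 16.32 A, I(0) = 0.9984 (r2 = 0.9972)
Porod-Debye plateau: absent
curves written to diag/
```

The same operations are available as library calls (`read_dat`, `fit_rgd`,
`entropy_error`, `kratky`, `classify_entropy`, …); `saxsflex batch` maps the
fit over a directory and writes a summary CSV with quartile labels.

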