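# jpet-effcal

Efficiency calibration for plastic-scintillator PET barrels.

Plastic strips register 511 keV annihilation photons only through Compton
scattering: every interaction deposits a continuous energy ΔE between zero
and the Compton edge (340 keV for 511 keV photons), and the probability
that the readout chain records a deposit — the **registration efficiency**
ξ(ΔE) — drops steeply toward the hardware threshold.  This package
implements, end to end, the calibration method that measures ξ(ΔE) without
an energy reference:

* a toy Compton-only Monte Carlo of a 3-layer, 192-strip scintillator
  barrel (back-to-back 511 keV pairs plus an isotropic 1274.6 keV prompt
  photon, Klein–Nishina scattering, published time/position/energy
  resolutions, a 70 keV threshold);
* the 3-hit coincidence analysis: two hits tagged as back-to-back primaries
  by their azimuthal correlation (the two smallest pairwise separations sum
  to 180°), the third hit assigned to its parent by the scatter test
  **S = Δt − D/c ≈ 0**, the annihilation vertex reconstructed from
  time-of-flight, and each event's scattering angle converted to an energy
  deposit via ΔE = E·[1 − 1/(1 + (E/511)(1 − cos θ))];
* the efficiency extraction: the deposit-spectrum ratio of a realistically
  thinned "detector" stream to a 100 %-efficient reference stream, fitted
  with the Boltzmann sigmoid ξ(E) = A1 + (A0−A1)/(1+exp((E−A2)/A3)), plus
  a per-event survival-model fit that removes the acceptance of the two
  accompanying hits from the recovered per-hit curve;
* the **intrinsic efficiency** versus incident energy,
  Eff(E) = ∫ f(ΔE;E)·ξ(ΔE) d(ΔE) with f the normalized Klein–Nishina
  deposition density, summarized by a Gaussian bell
  p0·exp(−(x−p1)²/(2p2²)) over 150–511 keV.

It is aimed at detector physicists who want a tested, seeded, fully
synthetic sandbox for this calibration chain — e.g. to study how threshold,
resolutions or selection cuts propagate into the recovered efficiency curve.

## Worked example

Simulate 8×10⁶ decays, thin the detector stream with the published
registration curve (A0=0.177, A1=0.996, A2=148.7 keV, A3=22.77 keV), run
the full selection on both streams and re-extract the curve:

```bash
jpet-effcal reproduce --seed 7 --n-events 8000000 --out demo/
```

which prints

```
recovered sigmoid: A0=0.144 A1=0.998 A2=144.0 keV A3=21.83 keV
report written to demo/report.json
```

`demo/report.json` holds the full record; for this run it contains

```
n_survival_sample: 1965          # matched 3-hit coincidences
n_selected_ideal: 771            # fully selected reference events
assignment accuracy: 97.41 %     # min-|S| scatter assignment vs truth (n=733)
recovered: A0=0.144 A1=0.998 A2=143.99 keV A3=21.83 keV
bell fit:  p0=0.58  p1=489.6 keV  p2=135.2 keV
```

Reading the numbers: from 8×10⁶ decays the 3-hit selection keeps 1965
matched coincidences; the survival-model fit returns the injected sigmoid
within its statistical errors at this small sample (A2 off by ~4.7 keV,
σ(A2)≈3.5 keV here; the default acceptance-scale run uses 8×10⁷ decays and
lands within ~1 keV).  The scatter test assigns the scattered photon to the
correct primary for ~98 % of cleanly labeled events, and the intrinsic
efficiency of the recovered curve peaks near 0.6 around 500 keV.  With
`--plots` the run also writes the angular-correlation, S-plane, spectrum,
ratio and intrinsic-efficiency figures.

The same stages are available individually (`simulate`, `select`,
`efficiency`, `intrinsic`) on CSV/JSON files, and as a library:

```python
from jpet_effcal import compton_edge, energy_deposit_pdf, bsf_eval
from jpet_effcal.constants import BSF_REFERENCE

compton_edge(511.0)              # 340.67 keV
bsf_eval(BSF_REFERENCE, 70.0)    # 0.202 -> 20 % efficiency at threshold
```

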