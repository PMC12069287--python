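# Fixture provenance

These CSV tables transcribe, value-for-value, the published measurement and
calibration tables for the shrub-branch DEM study (laboratory mechanical
test summaries, intrinsic parameters, screening/ascent/CCD designs, ANOVA
and the simulated-vs-actual comparison).  Printed anomalies are preserved
verbatim and marked in an `anomaly` column rather than silently corrected:

- `table1`: the compressive-force Min/Max pair (2073.56 / 1044.4) is
  evidently swapped as printed; the elastic/shear modulus standard
  deviations are printed without an evident unit scale.
- `table5`: the relative errors of runs 3 and 5 recompute to 6.92 / 6.03
  against the printed 6.93 / 6.02.  Footnote conditions: all contact
  parameters at their centre level, critical normal stress 5.005e9 Pa,
  bond radius 0.8 mm.
- `table7`: the quadratic bond-radius row prints sum-of-squares 18178.72
  but mean square 18178.12; the lack-of-fit p is 0.5818 in the table and
  0.6584 in the text.
- `table8`: the GA-BP-GA slope error recomputes to 0.23% against the
  printed 0.24%.

`table4`/`table6` carry coded levels exactly as printed; responses are the
means of three simulation repeats.
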