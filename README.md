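# isletmorph

Whole-pancreas islet morphometry: from multi-channel section images (or
per-islet measurement tables) to regional endocrine fractional-area
profiles, absolute beta/alpha/delta-cell mass, islet size/shape/
composition distributions, per-donor islet number and IEQ — plus a
synthetic donor generator with exact ground truth and a sampling-bias
simulator.

## Who this is for

Quantifying pancreatic beta-cell mass is central to diabetes research,
and historical estimates disagree partly because of method: sampling a
few blocks, selecting "islet-rich" fields, point-counting grids, and
population-based organ volumes all bias the result. `isletmorph`
implements the unbiased whole-organ workflow — every block, entire
sections, measured pancreas weight — as a tested Python library with a
thin CLI, so the same arithmetic can be applied to new section series
or studied on synthetic organs with known truth.

## The model in brief

- **Fractional-area stereology.** Per block, percent endocrine area
  `p_b = 100·E_b/A_b`; donor level, the tissue-weighted mean
  `p̄ = 100·ΣE_b/ΣA_b`. With the Delesse principle (area fraction =
  volume fraction) and tissue density ≈ 1 g/mL,
  `mass [mg] = p̄/100 × pancreas weight [g] × 1000`.
- **Cell-equivalent size scale.** Islet area / 178 µm² (one endocrine
  cell) gives a dimensionless count n; bin k spans `[2^(k−1), 2^k)`
  cells, i.e. effective diameters 30–42 µm (bin 3), 60–85 µm (bin 5),
  120–170 µm (bin 7).
- **Islet number.** `N = endocrine mass (mg·10⁻³) / islet volume
  (µm³·10⁻¹²)` per bin, with sphere-on-effective-diameter volumes;
  converted to IEQ (one IEQ = a 150 µm sphere) and checked against the
  clinical 400 K IEQ yield criterion.
- **Shape.** Circularity `4πA/P²` on sub-pixel contours and Feret
  diameter by rotating calipers.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Generate a synthetic donor at the default scale (24 blocks, ~0.7% mean
endocrine fraction, 100 g pancreas) and run the aggregation pipeline:

```python
import isletmorph as im

report, donor = im.run_synthetic_pipeline(im.GeneratorConfig(seed=1),
                                          table_only=True)
m = report.mass
print(f"beta: {m.pct_beta:.3f}% -> {m.mass_beta_mg:.1f} mg "
      f"(truth {donor.true_mass_mg['beta']:.1f} mg)")
print(report.counts.rounded()["total_ieq"])
```

prints

```
beta: 0.418% -> 418.1 mg (truth 418.1 mg)
396513
```

i.e. the measured beta-cell fractional area of 0.418% of tissue times
the 100 g organ gives 418 mg of beta-cells (matching the generator's
ground truth exactly in table mode), and the donor's endocrine volume
corresponds to ~397 K IEQ — just under the 400 K clinical isolation
threshold. The scripts in `examples/` walk through each capability
(simulation, image segmentation, regional profiles and mass, size
distributions, islet numbers, sampling bias) and print annotated
output; `isletmorph --help` lists the matching CLI subcommands
(`simulate | quantify | mass | sizedist | count | bias | report`).

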