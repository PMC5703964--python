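"""Head→tail regional profile and absolute beta/alpha/delta-cell mass.

Per-block percent fractional areas build the regional profile; the
tissue-weighted donor-level percent times pancreas weight (density
~1 g/mL) gives absolute mass in mg.
"""

import isletmorph as im

report, donor = im.run_synthetic_pipeline(im.GeneratorConfig(seed=1), table_only=True)

prof = report.profiles["endocrine"]
print(f"{len(report.blocks)} blocks; endocrine % per block "
      f"mean {prof.mean_pct:.3f} ± SEM {prof.sem_pct:.3f} "
      f"(tissue-weighted {prof.weighted_mean_pct:.3f})")
m = report.mass
print(f"beta  : {m.pct_beta:.3f}% -> {m.mass_beta_mg:7.1f} mg   "
      f"(truth {donor.true_mass_mg['beta']:.1f} mg)")
print(f"alpha : {m.pct_alpha:.3f}% -> {m.mass_alpha_mg:7.1f} mg")
print(f"delta : {m.pct_delta:.3f}% -> {m.mass_delta_mg:7.1f} mg")
print(f"endocrine total: {m.mass_endocrine_mg:.0f} mg "
      f"= {m.volume_endocrine_ul:.0f} uL at {m.density_g_per_ml} g/mL")
# In table mode the aggregation is exact, so recovered mass equals the
# generator's ground truth; with rendered images it agrees to <1%.
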