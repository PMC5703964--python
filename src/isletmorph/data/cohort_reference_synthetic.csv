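# isletmorph synthetic reference cohort v1
# SYNTHETIC stand-in table for a 10-donor whole-pancreas summary
# (age-matched non-diabetic adult males). Hand-built display data for
# report/plot smoke tests; NOT measurements and NOT pipeline output.
case,age_y,sex,bmi_kg_m2,height_cm,pancreas_weight_g,pct_beta,pct_alpha,pct_delta,mass_beta_mg,mass_alpha_mg,mass_delta_mg,mass_endocrine_mg
1,38.0,M,16.4,172,100,0.70,0.22,0.08,700.0,220.0,80.0,1000.0
2,41.5,M,31.4,178,130,0.55,0.22,0.08,715.0,286.0,104.0,1105.0
3,44.0,M,22.5,175,110,0.40,0.28,0.10,440.0,308.0,110.0,858.0
4,36.5,M,25.1,180,120,0.30,0.30,0.08,360.0,360.0,96.0,816.0
5,47.0,M,24.0,195,219,0.55,0.30,0.065,1204.5,657.0,142.4,2003.9
6,40.0,M,21.0,176,95,0.60,0.25,0.09,570.0,237.5,85.5,893.0
7,42.5,M,29.3,181,85,0.45,0.17,0.07,382.5,144.5,59.5,586.5
8,39.5,M,30.0,174,78,0.30,0.18,0.11,235.0,140.0,87.0,462.0
9,45.5,M,27.5,169,105,0.35,0.25,0.09,367.5,262.5,94.5,724.5
10,40.0,M,36.0,177,77,0.50,0.30,0.10,385.0,231.0,77.0,693.0
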