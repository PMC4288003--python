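# Rosuvastatin OATP1B1 genotype constants, Caucasian reference population.
# 35% of active uptake is NTCP; 77% of the remaining 65% is OATP1B1,
# so f_OATP1B1 = 0.65 * 0.77 = 0.5005 (~50%).  *1b/*15 intrinsic activity
# ratios 0.82 and 0.15; *1b expression twice *1a.
name: rosuvastatin-caucasian
frequencies:
  star1a: 0.56
  star1b: 0.26
  star15: 0.18
activity_ratio_1b: 0.82
activity_ratio_15: 0.15
expression_mult_1b: 2.0
expression_mult_15: 1.0
f_OATP1B1: 0.5005
ethnic_scalar: 1.0
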