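# Pravastatin OATP1B1 genotype constants, Caucasian reference population.
# 83% of total hepatic active uptake is OATP1B1-mediated; *1b/*15
# intrinsic activity ratios 0.81 and 0.35 (average of two in vitro
# reports); *1b protein expression is twice *1a; European haplotype
# frequencies *1a 56%, *1b 26%, *5/*15 18%.
name: pravastatin-caucasian
frequencies:
  star1a: 0.56
  star1b: 0.26
  star15: 0.18
activity_ratio_1b: 0.81
activity_ratio_15: 0.35
expression_mult_1b: 2.0
expression_mult_15: 1.0
f_OATP1B1: 0.83
ethnic_scalar: 1.0
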