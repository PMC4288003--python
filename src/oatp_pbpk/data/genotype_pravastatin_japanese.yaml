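# Pravastatin genotype constants with the Japanese/Caucasian intrinsic
# OATP1B1 activity ratio (0.584) applied to all active uptake clearances.
name: pravastatin-japanese
frequencies:
  star1a: 0.56
  star1b: 0.26
  star15: 0.18
activity_ratio_1b: 0.81
activity_ratio_15: 0.35
expression_mult_1b: 2.0
expression_mult_15: 1.0
f_OATP1B1: 0.83
ethnic_scalar: 0.584
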