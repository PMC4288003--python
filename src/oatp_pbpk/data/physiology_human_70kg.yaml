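# 70-kg reference human used for all shipped simulations.
# Volumes in L, flows in L/h; lung flow is cardiac output and equals the
# sum of the systemic tissue flows; "liver" flow is the hepatic artery
# (portal inflow = gut + spleen).  Values are package fixtures.
body_weight_kg: 70.0
tissue_volumes_L:
  lung: 0.53
  adipose: 14.0
  muscle: 29.0
  gut: 1.2
  spleen: 0.18
  kidney: 0.31
  liver: 1.8
  rest_of_body: 10.0
tissue_blood_flows_L_per_h:
  lung: 390.0
  adipose: 19.5
  muscle: 66.0
  gut: 52.0
  spleen: 11.7
  kidney: 72.0
  liver: 23.4
  rest_of_body: 145.4
volume_venous_blood_L: 3.4
volume_arterial_blood_L: 1.7
n_liver_subunits: 5
liver_blood_fraction: 0.2
bile_flow_mL_per_day: 350.0
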