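# Default kinetic parameter set (synthetic stand-in values).
#
# These are NOT fitted or published estimates.  They are order-of-magnitude
# plausible stand-ins assembled from general pharmacological reasoning:
# a fentanyl-like three-compartment opioid PK block, an intranasal naloxone
# transit-absorption block shaped like the labeled NARCAN concentration
# profile, and pM-scale competitive binding affinities chosen so that a
# 0.11 mg IV opioid bolus depresses ventilation below 25% of baseline and a
# 4 mg intranasal naloxone dose produces a clear reversal within one hour.
# Treat every number here as configuration, not as data.
#
# Units: PK rates 1/min, volumes L, clearance L/min, molar mass g/mol,
# binding k_on pM^-n s^-1, k_off s^-1.

opioid_binding:        # carfentanil-like agonist, Kd = k_off/k_on = 100 pM
  k_on: 2.0e-5
  k_off: 2.0e-3
  n: 1.0

naloxone_binding:      # antagonist, Kd = 150 pM
  k_on: 2.0e-4
  k_off: 3.0e-2
  n: 1.0

opioid_pk:             # three-compartment IV bolus, fentanyl-like shape
  k_out: 0.055
  k12: 0.373
  k21: 0.103
  k13: 0.180
  k31: 0.0146
  v_c: 12.7
  molar_mass: 394.5    # carfentanil
  k1_biophase: 0.10
  alpha: 1.0           # full agonist

naloxone_pk:           # two-transit-compartment intranasal absorption
  k_tr: 0.23
  k_in: 0.15
  v: 200.0
  c_l: 2.5
  f: 0.5
  molar_mass: 327.4
  k1_biophase: 0.15
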