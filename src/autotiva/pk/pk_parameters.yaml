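# Pharmacokinetic parameter registry, version 1.
#
# One block per drug. Each block gives the three-compartment micro rate
# constants (1/min), the central volume rule, and the default effect-site
# equilibration constant ke0 (1/min). Provenance of every constant is noted
# inline; these are the published parameter sets conventionally used by
# TCI pumps for each drug. ke0 values are configurable at run time because
# several conventions coexist in practice.
#
# Schema:
#   <drug>:
#     model: name of the published parameter set
#     source: citation of the primary publication
#     v1_per_kg | v1_model: central volume, L/kg of total body weight, or
#                           "minto" for the covariate model computed in code
#     k10..k31: micro rate constants (1/min) (fixed sets only)
#     ke0_default: 1/min, or "minto_age" for the age-dependent formula
#     ke0_alternatives: other values seen in practice, for config override

propofol:
  model: Marsh
  source: "Marsh B et al. Br J Anaesth 1991;67:41-48 (weight-proportional adult set)"
  v1_per_kg: 0.228        # L/kg
  k10: 0.119              # 1/min
  k12: 0.112
  k21: 0.055
  k13: 0.0419
  k31: 0.0033
  ke0_default: 1.21       # 1/min, "modified Marsh" pairing for effect-site targeting
                          # (Struys MMRF et al. Anesthesiology 2000;92:399-406)
  ke0_alternatives:
    diprifusor: 0.26      # classic Diprifusor pairing

remifentanil:
  model: Minto
  source: "Minto CF et al. Anesthesiology 1997;86:10-23 (covariate model, James LBM)"
  v1_model: minto         # V1..V3, Cl1..Cl3 from age/weight/height/sex in code
  ke0_default: minto_age  # ke0 = 0.595 - 0.007*(age-40) 1/min

rocuronium:
  model: Wierda
  source: "Wierda JM et al. Can J Anaesth 1991;38:430-435 (weight-proportional set)"
  v1_per_kg: 0.044        # L/kg
  k10: 0.10               # 1/min
  k12: 0.21
  k21: 0.13
  k13: 0.028
  k31: 0.01
  ke0_default: 0.168      # 1/min, conventional onset-matched value
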