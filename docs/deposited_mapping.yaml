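# Template column mapping for an externally deposited dataset.
#
# Copy this file next to the downloaded data (e.g. data/deposited/mapping.yaml),
# set each `file` to the deposited file name, and map every internal column
# name to the deposited header (columns already matching the internal name can
# be omitted).  `length_scale` rescales lengths to centimeters (e.g. 0.1 for
# data recorded in millimeters).
#
# Internal schema expected by clonalfish.deposited.load_deposited:
#   behavior : individual_id, day, activity_cm_per_s, feeding_min
#   sizes    : individual_id, age_days, length_cm
#   broods   : brood_id, individual_id, mother_id,
#              age_at_parturition_days, brood_size
#   offspring: brood_id, individual_id, offspring_length_cm

behavior:
  file: behavior.csv
  columns:
    individual_id: individual_id
    day: day
    activity_cm_per_s: activity_cm_per_s
    feeding_min: feeding_min

sizes:
  file: sizes.csv
  columns:
    individual_id: individual_id
    age_days: age_days
    length_cm: length_cm
  # length_scale: 0.1

broods:
  file: broods.csv
  columns:
    brood_id: brood_id
    individual_id: individual_id
    mother_id: mother_id
    age_at_parturition_days: age_at_parturition_days
    brood_size: brood_size

offspring:
  file: offspring.csv
  columns:
    brood_id: brood_id
    individual_id: individual_id
    offspring_length_cm: offspring_length_cm
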