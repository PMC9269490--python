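# Default geometry of the thoracolumbar multibody model, caudal -> cranial.
#
# body_height_cm: average adult vertebral body heights. The absolute values
# matter little for posture estimation because the chain is rescaled per
# subject from the tape-measured T1-L5 skin distance; what matters is the
# caudal-to-cranial profile (taller lumbar, shorter upper thoracic bodies).
# Override per subject via build_default_model(body_heights=...).
#
# spinous_length_anchor_cm: spinous-process lengths measured on the model at
# four anchor levels; intermediate levels are filled by monotone
# piecewise-cubic interpolation over vertebra index.
#
# soft_tissue_cm: soft-tissue thickness between spinous-process tip and skin,
# applied at every level; extra_tissue_cm adds the thicker gluteal/adipose
# layer of the lower lumbar region at L5 only.
schema: 1
body_height_cm:
  L5: 2.70
  L4: 2.80
  L3: 2.90
  L2: 2.85
  L1: 2.75
  T12: 2.60
  T11: 2.45
  T10: 2.30
  T9: 2.20
  T8: 2.10
  T7: 2.05
  T6: 2.00
  T5: 1.95
  T4: 1.90
  T3: 1.85
  T2: 1.85
  T1: 1.80
spinous_length_anchor_cm:
  L5: 4.5
  L1: 5.1
  T10: 4.6
  T1: 3.1
soft_tissue_cm: 1.35
extra_tissue_cm:
  L5: 1.7
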