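# Assumed 16-channel 10-20 montage for the field protocol.
#
# The acquisition device records 16 of 32 possible scalp positions; when
# hair obstructs a standard site the field team may move the electrode
# to a nearby alternate position.  The exact electrode names are an
# assumption of this package and are user-editable: pass a different
# YAML file to classify_montage / load_montage to override.
#
# "standard" lists the 16 canonical positions; "alternates" lists, for
# each standard position, the nonstandard neighbours accepted in its
# place.
standard:
  - Fp1
  - Fp2
  - F7
  - F3
  - F4
  - F8
  - T7
  - C3
  - C4
  - T8
  - P7
  - P3
  - P4
  - P8
  - O1
  - O2
alternates:
  Fp1: [AF3, AF7]
  Fp2: [AF4, AF8]
  F7: [F5, FT7]
  F3: [F1, FC3]
  F4: [F2, FC4]
  F8: [F6, FT8]
  T7: [C5, TP7]
  C3: [C1, FC1]
  C4: [C2, FC2]
  T8: [C6, TP8]
  P7: [P5, TP9]
  P3: [P1, CP3]
  P4: [P2, CP4]
  P8: [P6, TP10]
  O1: [PO3, PO7]
  O2: [PO4, PO8]
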