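# canonical straight drop-shape track and bench drive
track:
  drop_length_um: 30.0
  drop_width_um: 16.0
  neck_um: 15.0
  gap_um: 15.0
  n_units: 11
field:
  inplane_oe: 70.0
  vertical_oe: 70.0
  freq_hz: 0.2
particle:
  diameter_um: 5.5
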