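# Three-sequence 1.5 T fast MPF mapping protocol (times in seconds,
# angles in degrees, offset in Hz).
mtw:
  repetition_time: 0.020
  echo_time: 0.00476
  excitation_flip_angle: 8.0
  mt_pulse:
    envelope_shape: gaussian
    offset_frequency: 1500.0
    effective_flip_angle: 500.0
    duration: 0.00768
    truncation_level: 0.01
t1w:
  repetition_time: 0.016
  echo_time: 0.00476
  excitation_flip_angle: 18.0
pdw:
  repetition_time: 0.016
  echo_time: 0.00476
  excitation_flip_angle: 3.0
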