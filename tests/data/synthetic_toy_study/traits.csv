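species,head_rate,eye_movement,axial_length
sp01,36.5412,16.5347,13.7903
sp02,38.2024,15.4241,9.1712
sp03,23.6652,14.2125,10.9505
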