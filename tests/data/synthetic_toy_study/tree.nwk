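((sp01:0.25323119439612629,sp03:0.25323119439612629):0.74676880560387382,sp02:1);
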