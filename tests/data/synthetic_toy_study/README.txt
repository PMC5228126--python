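Synthetic toy study fixture (3 species, 1 retina each), generated by
`foveate simulate` with the config recorded below. Not derived from any
real retinal data.

mode: simulate
seed: 7
n_species: 3
retinas_per_species: [1, 1]
radius: 4.0
n_sites: 40
grid_step: 0.2
noise_cv: 0.05
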