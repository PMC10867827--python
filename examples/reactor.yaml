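# Example run configuration: 1 L acetate-fed up-flow packed bed column
# sampled at thirds of the cumulative volume.
reactor:
  id: upbr_acetate
  kind: plug_flow
  total_volume_L: 1.0
  zone_boundaries_L: [0.33, 0.66, 1.0]
feed:
  salts_g_per_L:
    sodium_acetate: 0.92     # -> 662 mg/L acetate anion at load time
  species_mg_per_L:
    sulfate: 1000.0
regime: acetate
ye_acetate_mg_per_L: 0.0     # acetate credit from yeast-extract oxidation,
                             # set only from an independent quantification
hrt_unit: h
fit:
  objective: conc
seed: 17
log_level: INFO
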