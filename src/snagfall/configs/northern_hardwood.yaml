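# Illustrative northern-hardwood-forest carbon budget (kg C per ha per yr).
# Round-number rates chosen to echo a mature north temperate hardwood stand:
# every value is overridable and none is a fitted quantity.
npp: 5000.0            # annual C input to live biomass
mortality_rate: 0.012  # fraction of live C dying per year
snag_fraction: 0.7     # share of mortality that forms snags (rest blows down)
litter_rate: 0.05      # fraction of live C shed as litter per year
k_litter: 0.4          # litter decay rate
k_snag: 0.04           # standing-deadwood decay rate (suspended, slow)
k_log: 0.12            # down-deadwood decay rate (ground contact, fast)
p_snag: 0.881          # annual snag persistence probability (baseline)
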