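indicator,rotation_delta,extent_delta,bau_baseline
corn_area_mha,2.8,,31.7
cropland_area_mha,,2.1,88.4
n2o_tg,2.8,1.3,48.6
n_applied_gg,480.0,237.3,9545.5
p_applied_gg,21.3,48.2,1986.4
nitrate_gg,87.1,47.9,2535.5
p_runoff_mg,203.2,439.0,19939.3
erosion_gg,222.9,633.9,18038.7
conversion_carbon_tg,,320.4,
forgone_sequestration_tg,,77.3,
corn_price_pct,,31.0,
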