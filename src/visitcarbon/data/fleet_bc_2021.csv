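fuel_type,vehicle_count,gco2e_per_km
gasoline,2950136,267.803
diesel,124739,272
battery_electric,48056,0
plug_in_hybrid,86066,99.4
other,196,
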