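route,description,one_way_km
Route1,Swartz Bay to Tsawwassen,44.45
Route2,Horseshoe Bay to Nanaimo,59.26
Route3,Tsawwassen to Duke Point,68.52
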