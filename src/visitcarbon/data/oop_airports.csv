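split_code,airport_code,name,share,roundtrip_tco2e
AB,YYC,Calgary International,0.5,0.25
AB,YEG,Edmonton International,0.5,0.28
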