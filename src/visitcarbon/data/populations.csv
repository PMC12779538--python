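region,population
Mainland/Southwest,3060000
Vancouver Island/Coast,880000
Thompson-Okanagan,600000
Kootenay,165000
Cariboo,160000
North Coast,55000
Nechako,40000
Northeast,70000
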