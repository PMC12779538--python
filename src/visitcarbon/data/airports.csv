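code,name,roundtrip_tco2e
YDL,Dease Lake,0.17
YYE,Fort Nelson,0.16
ZMT,Masset,0.12
YXJ,Fort St. John,0.12
YZP,Sandspit,0.11
YPR,Prince Rupert,0.11
YDQ,Dawson Creek,0.11
YXT,Terrace,0.10
YYD,Smithers,0.10
ZST,Stewart,0.09
TUX,Tumbler Ridge,0.09
CYCQ,Chetwynd,0.09
YPZ,Burns Lake,0.09
YRV,Revelstoke,0.09
CZAM,Salmon Arm,0.09
CYVK,Vernon Regional,0.09
YXC,Cranbrook/Canadian Rockies,0.09
YXS,Prince George,0.08
ZEL,Bella Bella,0.07
QBC,Bella Coola,0.06
YAA,Anahim Lake,0.06
YCG,Castlegar,0.06
YQZ,Quesnel,0.06
YWL,Williams Lake,0.05
YZT,Port Hardy,0.05
YYF,Penticton Regional,0.04
YKA,Kamloops,0.04
YLW,Kelowna International,0.04
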