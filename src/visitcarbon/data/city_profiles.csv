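city,region,long_haul,visit_weight,drive_km_to_hospital,ferry_route,drive_km_home_to_terminal,drive_km_terminal_to_hospital,airport_code,drive_km_home_to_airport,drive_km_airport_to_hospital
Vancouver,Mainland/Southwest,false,30,10,,,,,,
Surrey,Mainland/Southwest,false,20,30,,,,,,
Burnaby,Mainland/Southwest,false,10,8,,,,,,
Richmond,Mainland/Southwest,false,8,12,,,,,,
Abbotsford,Mainland/Southwest,false,6,70,,,,,,
Chilliwack,Mainland/Southwest,false,4,100,,,,,,
Gibsons,Mainland/Southwest,false,1,45,,,,,,
Victoria,Vancouver Island/Coast,false,5,68,Route1,32,36,,,
Nanaimo,Vancouver Island/Coast,false,3,30,Route2,5,25,,,
Courtenay,Vancouver Island/Coast,false,1.5,135,Route2,110,25,,,
Campbell River,Vancouver Island/Coast,false,1,180,Route2,155,25,,,
Kelowna,Thompson-Okanagan,true,5,390,,,,YLW,10,14
Kamloops,Thompson-Okanagan,true,4,355,,,,YKA,10,14
Vernon,Thompson-Okanagan,true,2,440,,,,CYVK,8,14
Penticton,Thompson-Okanagan,true,2,395,,,,YYF,5,14
Merritt,Thompson-Okanagan,false,0.8,270,,,,,,
Cranbrook,Kootenay,true,1.5,845,,,,YXC,10,14
Castlegar,Kootenay,true,1,605,,,,YCG,8,14
Williams Lake,Cariboo,true,1.5,540,,,,YWL,5,14
Quesnel,Cariboo,true,1,660,,,,YQZ,8,14
100 Mile House,Cariboo,false,0.8,455,,,,,,
Prince Rupert,North Coast,true,1.2,1500,,,,YPR,10,14
Terrace,North Coast,true,1.5,1350,,,,YXT,8,14
Burns Lake,Nechako,true,0.5,1100,,,,YPZ,5,14
Vanderhoof,Nechako,true,0.6,980,,,,YXS,100,14
Fort St. John,Northeast,true,1.2,1237,,,,YXJ,8,14
Dawson Creek,Northeast,true,0.8,1190,,,,YDQ,5,14
Calgary,Out of Province,true,1.2,970,,,,AB,20,14
Edmonton,Out of Province,true,1.0,1160,,,,AB,25,14
unidentified,Unknown,false,1,0,,,,,,
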