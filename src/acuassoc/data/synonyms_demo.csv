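raw_term,code,kind
Joksamni,ST36,acupoint
Hapgok,LI4,acupoint
Taechung,LR3,acupoint
Sameumgyo,SP6,acupoint
Jungwan,CV12,acupoint
Naegwan,PC6,acupoint
Dokbi,ST35,acupoint
Hyeolhae,SP10,acupoint
Taegye,KI3,acupoint
Buryu,KI7,acupoint
Sinsu,BL23,acupoint
Gyeoksu,BL17,acupoint
Danjung,CV17,acupoint
Baekhoe,GV20,acupoint
Pungnyung,ST40,acupoint
Sinmun,HT7,acupoint
Pungji,GB20,acupoint
blood disorder,U61,diagnosis
qi-blood-yin-yang deficiency,U62,diagnosis
fluid and humour,U63,diagnosis
liver excess,U65,diagnosis
kidney disease,U71,diagnosis
stomach disease,U73,diagnosis
qi deficiency,U60,diagnosis
heart deficiency,U66,diagnosis
heart excess,U67,diagnosis
spleen disease,U68,diagnosis
vertigo,R42,diagnosis
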