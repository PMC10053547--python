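names,mz_na,n_sugars
Holothurinoside N,1317.1,5
Holothurinoside M,1301.6,5
Girseaside A,1289.6,5
Impatinside B,1271.7,5
Holothurin A3,1259.3,4
Scabraside B|Holothurin A|17- or 25-dehydroechinoside A,1243.3,4
Holothurin A2,1229.5,4
Scabraside A|Fuscocineroside B/C|24-dehydroechinoside A,1227.5,4
Unidentified,1211,4
Desholothurin A|Desholothurin A1,1141.5,4
Holothurinoside C,1125.6,4
Unidentified,1109,4
Leucospilotaside A,921.4,2
Holothurin B4|Nobiliside B|Holothurin B,905.4,2
Holothurin B3,889.4,2
Unidentified,873,2
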