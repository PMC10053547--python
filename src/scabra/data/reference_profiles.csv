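sample_id,attractive,detected_mz
H. scabra juvenile integument,1,1259.3 1243.3 1227.5 1211 1141.5 1125.6 1109 905.4 889.4 873
H. scabra starved juvenile integument,0,1259.3 1243.3 1227.5 1141.5 1125.6 1109
H. scabra adult viscera,1,1259.3 1243.3 1227.5 1141.5 905.4 889.4
H. scabra adult conditioned water,0,1243.3 1229.5 1227.5 1125.6
H. leucospilota BW mucus,1,1317.1 1301.6 1289.6 1271.7 1259.3 1243.3 1227.5 1141.5 921.4 905.4 889.4
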