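{
 "GADPH": "GAPDH",
 "PRS27A": "RPS27A",
 "B7-1": "CD80",
 "4-1BBL": "TNFSF9",
 "LIGHT": "TNFSF14",
 "HVEM": "TNFRSF14",
 "B7-DC": "PDCD1LG2",
 "galectin 9": "LGALS9",
 "CD112": "NECTIN2",
 "H2-Abl": "H2-Ab1",
 "Mrl": "Mr1",
 "CCLL5": "CCL15",
 "L12RB1": "IL12RB1",
 "L13": "IL13",
 "IL7B": "IL17B",
 "L10RB": "IL10RB"
}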