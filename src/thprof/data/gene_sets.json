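{
 "mhc2_mouse": {
  "description": "14 mouse MHC class II molecules (antigen presentation, T-cell activation signal 1)",
  "genes": [
   "Cd74",
   "Ciita",
   "H2-Aa",
   "H2-Ab1",
   "H2-DMa",
   "H2-DMb1",
   "H2-DMb2",
   "H2-Ea-ps",
   "H2-Eb1",
   "H2-Eb2",
   "H2-K1",
   "H2-Oa",
   "H2-Ob",
   "Mr1"
  ],
  "complete": true
 },
 "cosignal_partial": {
  "description": "Partial panel of APC co-signaling receptors (T-cell activation signal 2). INCOMPLETE: the full 28-receptor panel is published only as a figure; only the receptors named in running text are packaged.",
  "genes": [
   "LIGHT",
   "4-1BBL",
   "CD48",
   "B7-1",
   "CD112",
   "galectin 9",
   "B7-DC",
   "HVEM"
  ],
  "complete": false,
  "directionality": {
   "LIGHT": "co-stimulation",
   "4-1BBL": "co-stimulation",
   "CD48": "co-stimulation",
   "B7-1": "co-stimulation",
   "CD112": "co-stimulation",
   "galectin 9": "co-inhibition",
   "B7-DC": "co-inhibition",
   "HVEM": "co-inhibition"
  }
 },
 "housekeeping_human": {
  "description": "Human housekeeping panel used for the mean+2SD expression threshold (symbols as printed in the source)",
  "genes": [
   "PRS27A",
   "GADPH",
   "ARHGDIA"
  ],
  "complete": true
 },
 "housekeeping_mouse": {
  "description": "Mouse housekeeping panel used for the mean+2SD expression threshold",
  "genes": [
   "Ldha",
   "Nono",
   "Rpl32"
  ],
  "complete": true
 }
}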