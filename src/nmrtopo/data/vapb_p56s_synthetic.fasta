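>vapb_p56s_synthetic SYNTHETIC stand-in for full-length VAPB (243 aa), NOT the natural sequence; built to honour published residue anchors, amphiphilic MSP helices and a hydrophobic C-terminal transmembrane helix; P56S variant
MAKLEQVADGSNTPSGEKSDSFKDLLEKLLKLGSNDGKTDCSDVESTNGSDKCNASDQTK
ITGDASENVSVNTQGFDSTEGNKSDHSDMVASMANGTDKALMEAFKKASGTSEPSDLLKE
CLKKLKGSEQSKEGSEKTVSPSQSDKPAENSGSEEKSGSQDKTESAPKSESQSGSDKETN
PSAGSEKSDQSEGSNKTESGSQSKDPSNKWSKNSEKQSPLLFVLIALVIGLAFLVIGLYF
KKR
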