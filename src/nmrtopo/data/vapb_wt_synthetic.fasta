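>vapb_wt_synthetic SYNTHETIC stand-in for full-length VAPB (243 aa), NOT the natural sequence; built to honour published residue anchors, amphiphilic MSP helices and a hydrophobic C-terminal transmembrane helix; wild-type (Pro56) variant
MAKLEQVADGSNTPSGEKSDSFKDLLEKLLKLGSNDGKTDCSDVESTNGSDKCNAPDQTK
ITGDASENVSVNTQGFDSTEGNKSDHSDMVASMANGTDKALMEAFKKASGTSEPSDLLKE
CLKKLKGSEQSKEGSEKTVSPSQSDKPAENSGSEEKSGSQDKTESAPKSESQSGSDKETN
PSAGSEKSDQSEGSNKTESGSQSKDPSNKWSKNSEKQSPLLFVLIALVIGLAFLVIGLYF
KKR
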