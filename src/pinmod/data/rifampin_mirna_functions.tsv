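term	mirnas
Response to drug	miR-34b,miR-886-3p,miR-218,miR-576-3p,miR-200c
Metabolism of xenobiotics by cytochrome P450	miR-335
Drug metabolism	miR-335
Linoleic acid metabolism	miR-335
Pathways in cancer	miR-186,miR-95,miR-769
Focal adhesion	miR-34b,miR-886-3p,miR-218,miR-576-3p,miR-200c,miR-616,miR-660,miR-335,miR-92a
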