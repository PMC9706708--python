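# SR6 six-bin amino-acid recoding (Susko & Roger 2007).
A: APST
B: DENG
C: QKR
D: MIVL
E: WC
F: FYH
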