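# KGB6 six-bin amino-acid recoding (Kosiol, Goldman & Buttimore 2004).
A: AGPS
B: DENQHKRT
C: MIL
D: W
E: FY
F: CV
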