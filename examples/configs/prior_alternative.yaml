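a: 6.0
b: 4.0
a_lambda: 2.0
b_lambda: 0.01
a_gamma: 3.0
b_gamma: 0.05
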