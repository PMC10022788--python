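a: 1.0
b: 0.1
a_lambda: 1.0
b_lambda: 0.1
a_gamma: 1.0
b_gamma: 0.01
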