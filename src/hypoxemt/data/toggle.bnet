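name: toggle
A *= not B
B *= not A
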