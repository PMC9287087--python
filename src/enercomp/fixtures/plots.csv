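plot,treatment
4,control
11,control
14,control
17,control
3,exclosure
15,exclosure
19,exclosure
20,exclosure
21,exclosure
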