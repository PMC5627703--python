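startage:20
stopage:21
interval:1
number:1000
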