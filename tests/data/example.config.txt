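startage:12
stopage:80
interval:2
number:5
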