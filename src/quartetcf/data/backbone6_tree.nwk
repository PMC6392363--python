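(O:3,((A:1,B:1):1,(E:1.5,(C:1,D:1):0.5):1):1);
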