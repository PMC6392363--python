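(O:1,((A:1,(H:1)#H1:0::0.5):5,(B:1,#H1:0::0.5):5):1);
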