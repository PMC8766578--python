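# Tokens in the entry description that veto the soda label (diet drinks are not
# sugary soda). Matched as whole tokens of the normalized description.
diet
lite
light
zero
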