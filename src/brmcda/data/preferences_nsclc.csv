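alternative,kps,ca211,cea,fatigue,gi_adverse
experimental,82,67,75,66,56
control,18,33,25,36,24
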