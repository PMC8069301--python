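# Dementia-umbrella UMLS CUIs (broad neurodegenerative category)
C0524851
C0002736
C0030567
C0002395
C0020179
C0497327
C0338656
C0011265
C0038454
C0242422
C0233794
C0026769
C0338451
C0752347
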