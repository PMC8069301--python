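# Obstructive-sleep-apnea-related UMLS CUIs
C0520679
C0037315
C0520680
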