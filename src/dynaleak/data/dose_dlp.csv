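scan_phase,dlp_mgycm
non_contrast,365.5
arterial,241.2
delayed,241.0
triphasic_total,829.0
dynamic,1063.8
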