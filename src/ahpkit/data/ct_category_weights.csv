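category_id,radiology,ear_surgery,neurology,emergency_neurology,emergency
performance,0.22,0.44,0.39,0.19,0.18
safety,0.48,0.34,0.29,0.57,0.60
usability,0.19,0.14,0.22,0.17,0.13
technical_issues,0.11,0.08,0.10,0.08,0.09
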