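node_id,radiology,ear_surgery,neurology,emergency_neurology,emergency
performance,0.00,0.04,0.03,0.00,0.01
safety,0.00,0.00,0.00,0.01,0.03
usability,0.10,0.01,0.00,0.03,0.00
technical_issues,0.00,0.00,0.00,0.03,0.00
ct_scanner,0.01,0.07,0.06,0.04,0.02
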