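birth_weight,preterm,term,postterm
LBW,111,102,0
normal,131,3928,19
macrosomia,2,119,3
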