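package_id,rate_inr
major_general_surgery,1100000
orthopedic_trauma,900000
obstetric_surgery,500000
minor_procedures,383988
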