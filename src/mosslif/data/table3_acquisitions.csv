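laser,filter
CoCoBi—532 nm and 355 nm,None
CoCoBi—532 nm,355 nm
CoCoBi—355 nm,532 nm
Chl-SL—A 445 nm,None
Chl-SL—A 445 nm,650—chl-b
Chl-SL—A 445 nm,670—chl-a
Chl-SL—B 462 nm,None
Chl-SL—B 462 nm,650—chl-b
Chl-SL—B 462 nm,670—chl-a
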