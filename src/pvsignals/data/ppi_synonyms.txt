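# Proton-pump inhibitors
OMEPRAZOLE
PANTOPRAZOLE
ESOMEPRAZOLE
LANSOPRAZOLE
RABEPRAZOLE
DEXLANSOPRAZOLE
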