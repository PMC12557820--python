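# SYNTHETIC stand-in for the EMA designated-medical-events (DME) list
# (rare, serious, likely drug-induced events).  The real list is published
# by the EMA under its own terms; supply it via the dme_list config key.
DRUG-INDUCED LIVER INJURY
RENAL FAILURE
DEAFNESS
VANISHING BILE DUCT SYNDROME
HEPATITIS FULMINANT
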