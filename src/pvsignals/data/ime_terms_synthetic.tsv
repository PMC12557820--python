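# SYNTHETIC stand-in for the EMA important-medical-events (IME) list.
# The real list is published by the EMA under its own terms and is not
# redistributed here; supply it via the ime_list configuration key.
# One preferred term per line; matching is case-insensitive.
PNEUMONIA
SEPSIS
RENAL FAILURE
RENAL IMPAIRMENT
DEAFNESS
DRUG-INDUCED LIVER INJURY
HEPATIC FUNCTION ABNORMAL
JAUNDICE
CHOLESTASIS
VANISHING BILE DUCT SYNDROME
PULMONARY ALVEOLAR HEMORRHAGE
CYTOMEGALOVIRUS INFECTION
DEEP VEIN THROMBOSIS
MULTIPLE ORGAN DYSFUNCTION SYNDROME
INTERSTITIAL LUNG DISEASE
HEPATITIS FULMINANT
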