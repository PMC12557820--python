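pt	soc
ABDOMINAL DISCOMFORT	GASTROINTESTINAL DISORDERS
ALANINE AMINOTRANSFERASE INCREASED	INVESTIGATIONS
ALOPECIA	SKIN AND SUBCUTANEOUS TISSUE DISORDERS
BLOOD CREATININE INCREASED	INVESTIGATIONS
CHOLESTASIS	HEPATOBILIARY DISORDERS
COUGH	RESPIRATORY, THORACIC AND MEDIASTINAL DISORDERS
COVID-19	INFECTIONS AND INFESTATIONS
CYTOMEGALOVIRUS INFECTION	INFECTIONS AND INFESTATIONS
DEAFNESS	EAR AND LABYRINTH DISORDERS
DEATH	GENERAL DISORDERS AND ADMINISTRATION SITE CONDITIONS
DEEP VEIN THROMBOSIS	VASCULAR DISORDERS
DIALYSIS	SURGICAL AND MEDICAL PROCEDURES
DIARRHEA	GASTROINTESTINAL DISORDERS
DIZZINESS	NERVOUS SYSTEM DISORDERS
DRUG-INDUCED LIVER INJURY	HEPATOBILIARY DISORDERS
DYSPNOEA	RESPIRATORY, THORACIC AND MEDIASTINAL DISORDERS
FALL	INJURY, POISONING AND PROCEDURAL COMPLICATIONS
FATIGUE	GENERAL DISORDERS AND ADMINISTRATION SITE CONDITIONS
HEADACHE	NERVOUS SYSTEM DISORDERS
HEPATIC ENZYME INCREASED	INVESTIGATIONS
HEPATIC FUNCTION ABNORMAL	HEPATOBILIARY DISORDERS
HYPERTENSION	VASCULAR DISORDERS
ILLNESS	GENERAL DISORDERS AND ADMINISTRATION SITE CONDITIONS
INFECTION	INFECTIONS AND INFESTATIONS
JAUNDICE	HEPATOBILIARY DISORDERS
LIVER DISORDER	HEPATOBILIARY DISORDERS
NAUSEA	GASTROINTESTINAL DISORDERS
OFF LABEL USE	INJURY, POISONING AND PROCEDURAL COMPLICATIONS
PNEUMONIA	INFECTIONS AND INFESTATIONS
PROTEINURIA	RENAL AND URINARY DISORDERS
PULMONARY ALVEOLAR HEMORRHAGE	RESPIRATORY, THORACIC AND MEDIASTINAL DISORDERS
PYREXIA	GENERAL DISORDERS AND ADMINISTRATION SITE CONDITIONS
RASH	SKIN AND SUBCUTANEOUS TISSUE DISORDERS
RENAL FAILURE	RENAL AND URINARY DISORDERS
RENAL IMPAIRMENT	RENAL AND URINARY DISORDERS
SEPSIS	INFECTIONS AND INFESTATIONS
SURGERY	SURGICAL AND MEDICAL PROCEDURES
URINARY TRACT INFECTION	INFECTIONS AND INFESTATIONS
VANISHING BILE DUCT SYNDROME	HEPATOBILIARY DISORDERS
VOMITING	GASTROINTESTINAL DISORDERS
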