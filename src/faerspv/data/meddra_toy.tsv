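pt	soc
Injection site pain	General disorders and administration site conditions
Injection site erythema	General disorders and administration site conditions
Injection site pruritus	General disorders and administration site conditions
Injection site reaction	General disorders and administration site conditions
Injection site urticaria	General disorders and administration site conditions
Injection site rash	General disorders and administration site conditions
Injection site swelling	General disorders and administration site conditions
Injection site bruising	General disorders and administration site conditions
Injection site mass	General disorders and administration site conditions
Injection site warmth	General disorders and administration site conditions
Pyrexia	General disorders and administration site conditions
Condition aggravated	General disorders and administration site conditions
Malaise	General disorders and administration site conditions
Illness	General disorders and administration site conditions
Swelling	General disorders and administration site conditions
Inflammation	General disorders and administration site conditions
Fatigue	General disorders and administration site conditions
Chills	General disorders and administration site conditions
Infection	Infections and infestations
Sinusitis	Infections and infestations
Influenza	Infections and infestations
Cellulitis	Infections and infestations
Nasopharyngitis	Infections and infestations
Pneumonia	Infections and infestations
Septic shock	Infections and infestations
Sepsis	Infections and infestations
Intestinal sepsis	Infections and infestations
Measles	Infections and infestations
Necrotising fasciitis streptococcal	Infections and infestations
Urinary tract infection	Infections and infestations
Upper respiratory tract infection	Infections and infestations
Tuberculosis	Infections and infestations
Urticaria	Skin and subcutaneous tissue disorders
Rash	Skin and subcutaneous tissue disorders
Pruritus	Skin and subcutaneous tissue disorders
Erythema	Skin and subcutaneous tissue disorders
Alopecia	Skin and subcutaneous tissue disorders
Contusion	Injury, poisoning and procedural complications
Fall	Injury, poisoning and procedural complications
Overdose	Injury, poisoning and procedural complications
Off label use	Injury, poisoning and procedural complications
Arthralgia	Musculoskeletal and connective tissue disorders
Joint swelling	Musculoskeletal and connective tissue disorders
Arthritis	Musculoskeletal and connective tissue disorders
Myalgia	Musculoskeletal and connective tissue disorders
Back pain	Musculoskeletal and connective tissue disorders
Rheumatoid arthritis	Musculoskeletal and connective tissue disorders
Still's disease	Musculoskeletal and connective tissue disorders
Juvenile idiopathic arthritis	Musculoskeletal and connective tissue disorders
Abdominal pain	Gastrointestinal disorders
Nausea	Gastrointestinal disorders
Vomiting	Gastrointestinal disorders
Diarrhoea	Gastrointestinal disorders
Mouth ulceration	Gastrointestinal disorders
Inflammatory bowel disease	Gastrointestinal disorders
Cough	Respiratory, thoracic and mediastinal disorders
Oropharyngeal pain	Respiratory, thoracic and mediastinal disorders
Rhinorrhoea	Respiratory, thoracic and mediastinal disorders
Nasal congestion	Respiratory, thoracic and mediastinal disorders
Dyspnoea	Respiratory, thoracic and mediastinal disorders
Pulmonary embolism	Respiratory, thoracic and mediastinal disorders
Acute respiratory distress syndrome	Respiratory, thoracic and mediastinal disorders
Pulmonary oedema	Respiratory, thoracic and mediastinal disorders
C-reactive protein increased	Investigations
Serum ferritin increased	Investigations
Haemoglobin decreased	Investigations
Alanine aminotransferase increased	Investigations
Lymphadenopathy	Blood and lymphatic system disorders
Anaemia	Blood and lymphatic system disorders
Pancytopenia	Blood and lymphatic system disorders
Haemophagocytic lymphohistiocytosis	Blood and lymphatic system disorders
Headache	Nervous system disorders
Dizziness	Nervous system disorders
Palpitations	Cardiac disorders
Thrombosis	Vascular disorders
Shock	Vascular disorders
Hepatomegaly	Hepatobiliary disorders
Hepatocellular injury	Hepatobiliary disorders
Hepatosplenomegaly	Hepatobiliary disorders
Insomnia	Psychiatric disorders
Anxiety	Psychiatric disorders
Cryopyrin-associated periodic syndrome	Congenital, familial and genetic disorders
Product used for unknown indication	Surgical and medical procedures
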