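"""Small bundled clinical vocabulary used by the synthetic code space and the
built-in document generator.  Deliberately generic: the point is surface
structure (conditions, variants, concrete concepts), not clinical realism."""

# Base condition phrases, one per synthetic code family.
CONDITIONS = [
    "type 1 diabetes mellitus",
    "migraine",
    "retinal disorder",
    "vestibular dysfunction",
    "superficial head injury",
    "skull fracture",
    "intracranial injury",
    "cardiac device complication",
    "joint prosthesis complication",
    "graft complication",
    "anemia",
    "esophageal reflux",
    "heart failure",
    "chronic kidney disease",
    "asthma",
    "atrial fibrillation",
    "pneumonia",
    "urinary tract infection",
    "cellulitis",
    "hypothyroidism",
    "sepsis",
    "pancreatitis",
    "cholelithiasis",
    "epilepsy",
]

# Variant phrases distinguishing leaves within a family.  The distinctive
# token (used as the learnable trigger) is the first word of each phrase.
VARIANTS = [
    "with ketoacidosis",
    "with nephropathy",
    "with retinopathy",
    "with neuropathy",
    "with hypoglycemia",
    "with hyperosmolarity",
    "intractable form",
    "chronic course",
    "recurrent episodes",
    "acute exacerbation",
    "bilateral involvement",
    "posterior segment",
    "displaced pattern",
    "nondisplaced pattern",
    "initial encounter",
    "subsequent encounter",
    "mechanical breakdown",
    "embolic sequela",
    "infectious sequela",
    "stenotic sequela",
    "hemorrhagic component",
    "ischemic component",
    "refractory state",
    "compensated state",
]

# Concrete concepts substituted for "Other ..." umbrella descriptions.
SPECIFIC_CONCEPTS = [
    "recurrent corneal erosion",
    "nocturnal leg cramps",
    "transient global amnesia",
    "benign positional vertigo",
    "localized lymphadenopathy",
    "solitary pulmonary nodule",
    "postprocedural seroma",
    "medication-induced tremor",
]

# Noise sentences for narrative filler.
FILLER_SENTENCES = [
    "Vital signs remained stable throughout the admission.",
    "The patient tolerated a regular diet prior to discharge.",
    "Physical therapy evaluated the patient and recommended outpatient follow up.",
    "Home medications were reconciled on discharge.",
    "The patient was counselled on warning signs requiring urgent review.",
    "Laboratory values trended toward baseline before discharge.",
    "Repeat imaging showed interval improvement.",
    "The nursing team reported no overnight events.",
]

SOCIAL_HISTORY_SENTENCES = [
    "The patient lives alone and is independent in activities of daily living.",
    "The patient is a former smoker and quit several years ago.",
    "The patient denies alcohol or recreational drug use.",
    "The patient lives with family who assist with daily care.",
]

FAMILY_HISTORY_SENTENCES = [
    "Family history is notable for cardiovascular disease.",
    "There is a family history of diabetes in a first-degree relative.",
    "Family history is noncontributory.",
    "A sibling carries a diagnosis of hypertension.",
]
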