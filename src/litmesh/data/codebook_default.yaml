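# Default codebook: MeSH-level inclusion/exclusion rules and WHO
# social-determinants-framework categories.  Users may ship their own.
#
# inclusion: at least one of these cardiovascular-disease descriptors must
#   be present for a record to enter the corpus.
# exclusion: presence of any of these (other-disease) descriptors rejects
#   the record.
# risk_factors: classic cardiovascular risk factors; a record whose only
#   non-demographic, non-CVD content is in this list is rejected, but the
#   terms themselves remain legitimate network nodes.
# demographics: check-tag style descriptors ignored by the risk-factor rule.
# stoplist: descriptors removed before network construction.
# stoplist_countries: also stop-list every country name in the gazetteer.

inclusion:
  - Acute Coronary Syndrome
  - Myocardial Infarction
  - Heart Diseases
  - Angina Pectoris

exclusion:
  - Rheumatic Fever
  - Lung Diseases
  - Lupus Erythematosus
  - Neoplasms
  - Pneumonia
  - Dementia
  - Parkinson Disease

risk_factors:
  - Obesity
  - Smoking
  - Physical Inactivity
  - Diabetes Mellitus
  - Stress
  - Metabolic Syndrome
  - Hypertension
  - Cholesterol

demographics:
  - Female
  - Male
  - Middle Aged
  - Adult
  - Aged
  - Adolescent
  - Child
  - Young Adult

stoplist:
  - Humans
  - Human Beings
  - Statistical Analysis
  - Methods

stoplist_countries: true

categories:
  structural-context:
    - Social Determinants of Health
    - Health Policy
    - Public Policy
    - Public Health
    - Politics
    - Culture
    - Social Values
    - Government
    - World Health Organization
    - Global Health
    - Environment
  structural-position:
    - Socioeconomic Factors
    - Social Class
    - Poverty
    - Education
    - Income
    - Occupations
    - Employment
    - Health Status Disparities
    - Residence Characteristics
    - Ethnic Groups
    - Sex Factors
  intermediary-health-system:
    - Health Promotion
    - Health Services Accessibility
    - Health Services Needs and Demand
    - Health Services, Indigenous
    - Delivery of Health Care
    - Insurance, Health
  intermediary-other:
    - Life Style
    - Risk Factors
    - Smoking
    - Obesity
    - Diabetes Mellitus
    - Hypertension
    - Stress
    - Metabolic Syndrome
    - Cholesterol
    - Physical Inactivity
    - Aging
    - Health Status
    - Child Development
    - Food Supply
    - Housing
    - Social Support
    - Social Environment
  cvd-outcome:
    - Acute Coronary Syndrome
    - Myocardial Infarction
    - Heart Diseases
    - Angina Pectoris
    - Cardiovascular Diseases
    - Coronary Disease
    - Stroke
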