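E75.2,Other sphingolipidosis (includes Fabry disease)
I42,Cardiomyopathy
I42.1,Obstructive hypertrophic cardiomyopathy
I42.2,Other hypertrophic cardiomyopathy
I21,Acute myocardial infarction
I22,Subsequent myocardial infarction
I25.2,Old myocardial infarction
I44,Atrioventricular and left bundle-branch block
I45,Other conduction disorders
I46,Cardiac arrest
I47,Paroxysmal tachycardia
I48,Atrial fibrillation and flutter
I49,Other cardiac arrhythmias
N18,Chronic kidney disease
N19,Unspecified kidney failure
R80,Isolated proteinuria
L74.4,Anhidrosis
I63,Cerebral infarction
I64,Stroke not specified as haemorrhage or infarction
G45,Transient cerebral ischaemic attacks and related syndromes
H90,Conductive and sensorineural hearing loss
H91,Other hearing loss
K58,Irritable bowel syndrome
K59,Other functional intestinal disorders
R10,Abdominal and pelvic pain
R50,Fever of other and unknown origin
H18.0,Corneal pigmentations and deposits
H35,Other retinal disorders
N08,Glomerular disorders in diseases classified elsewhere
E85,Amyloidosis
D86,Sarcoidosis
Q87.8,Other specified congenital malformation syndromes
Z90.5,Acquired absence of kidney
N20,Calculus of kidney and ureter
Q61,Cystic kidney disease
Q21.1,Atrial septal defect
S06,Intracranial injury
Z51.5,Palliative care
F10,Mental and behavioural disorders due to use of alcohol
C78,Secondary malignant neoplasm of respiratory and digestive organs
C79,Secondary malignant neoplasm of other sites
C80,Malignant neoplasm without specification of site
C81,Hodgkin lymphoma
C82,Follicular lymphoma
C83,Non-follicular lymphoma
C84,Mature T/NK-cell lymphomas
C85,Other and unspecified types of non-Hodgkin lymphoma
C90,Multiple myeloma and malignant plasma cell neoplasms
C91,Lymphoid leukaemia
C92,Myeloid leukaemia
C93,Monocytic leukaemia
C94,Other leukaemias of specified cell type
C95,Leukaemia of unspecified cell type
C96,Other malignant neoplasms of lymphoid and haematopoietic tissue
Z51.1,Chemotherapy session for neoplasm
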