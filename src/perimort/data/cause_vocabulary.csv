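axis,code,label,version
maternal,M1,"Complications of placenta, cord and membranes",starter-1.0
maternal,M2,"Maternal complications of pregnancy",starter-1.0
maternal,M3,"Other complications of labour and delivery",starter-1.0
maternal,M4,"Maternal medical and surgical conditions",starter-1.0
maternal,M5,"No maternal condition identified",starter-1.0
placental,P1,"Maternal vascular malperfusion",starter-1.0
placental,P2,"Fetal vascular malperfusion",starter-1.0
placental,P3,"Acute chorioamnionitis",starter-1.0
placental,P4,"Chronic inflammatory lesions",starter-1.0
placental,P5,"Abruption / retroplacental hemorrhage",starter-1.0
placental,P6,"Umbilical cord accident",starter-1.0
fetal_neonatal,F1,"Congenital malformations, deformations and chromosomal abnormalities",starter-1.0
fetal_neonatal,F2,"Disorders related to fetal growth",starter-1.0
fetal_neonatal,F3,"Birth trauma",starter-1.0
fetal_neonatal,F4,"Complications of intrapartum events (asphyxia)",starter-1.0
fetal_neonatal,F5,"Infection",starter-1.0
fetal_neonatal,F6,"Respiratory and cardiovascular disorders",starter-1.0
fetal_neonatal,F7,"Low birth weight and prematurity",starter-1.0
fetal_neonatal,F8,"Other and unspecified causes",starter-1.0
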