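sku,name,category,application
N1148,NBD cholesterol,Lipid metabolism and trafficking,Sterol lipids
D3922,BODIPY 493,Lipid metabolism and trafficking,Neutral lipids
H34475,HCS LipidTOX Green,Lipid metabolism and trafficking,Neutral lipids
D3921,BODIPY 505,Lipid metabolism and trafficking,Neutral lipids
D3821,BODIPY FL C16,Lipid metabolism and trafficking,Fatty acyls
D3822,BODIPY FL C12,Lipid metabolism and trafficking,Fatty acyls
N3786,NBD C6-HPC,Lipid metabolism and trafficking,Glycerophospholipids
V12390,BODIPY FL vinblastine,Drug conjugate,Tubulin staining
D3834,BODIPY FL C5,Lipid metabolism and trafficking,Fatty acyls
D3803,BODIPY FL C5-HPC,Lipid metabolism and trafficking,Glycerophospholipids
D7711,BODIPY FL C12 sphingomyelin,Lipid metabolism and trafficking,Sphingolipids
N1154,NBD C6 ceramide,Lipid metabolism and trafficking,Sphingolipids
P6763,Phen Green FL diacetate,Ion concentration,Heavy metals
X1001,Synthetic lipid probe A,Lipid metabolism and trafficking,Phospholipids
X1002,Synthetic lipid probe B,Lipid metabolism and trafficking,Glycerolipids
X1003,Synthetic lipid probe C,Lipid metabolism and trafficking,Sterol lipids
X2001,Synthetic organelle probe A,Organelle morphology,Mitochondria
X2002,Synthetic organelle probe B,Organelle morphology,Lysosomes
X2003,Synthetic organelle probe C,Organelle morphology,Endoplasmic reticulum
X2004,Synthetic organelle probe D,Organelle morphology,Golgi apparatus
X2005,Synthetic organelle probe E,Organelle morphology,Actin cytoskeleton
X2006,Synthetic organelle probe F,Organelle morphology,Tubulin cytoskeleton
X2007,Synthetic organelle probe G,Organelle morphology,Early endosomes
X2008,Synthetic organelle probe H,Organelle morphology,Late endosomes
X2009,Synthetic organelle probe I,Organelle morphology,Autophagosomes
X2010,Synthetic organelle probe J,Organelle morphology,Peroxisomes
X2011,Synthetic organelle probe K,Organelle morphology,Plasma membrane
X2012,Synthetic organelle probe L,Organelle morphology,Nucleolus
X2013,Synthetic organelle probe M,Organelle morphology,Mitochondrial membrane potential
X2014,Synthetic organelle probe N,Organelle morphology,Acidic vesicles
X3001,Synthetic ion probe A,Ion concentration,Calcium
X3002,Synthetic ion probe B,Ion concentration,Zinc
X3003,Synthetic ion probe C,Ion concentration,Magnesium
X3004,Synthetic ion probe D,Ion concentration,Sodium
X3005,Synthetic ion probe E,Ion concentration,Potassium
X3006,Synthetic ion probe F,Ion concentration,pH
X3007,Synthetic ion probe G,Ion concentration,Chloride
X4001,Synthetic stress probe A,Cellular stress,Reactive oxygen species
X4002,Synthetic stress probe B,Cellular stress,Glutathione
X4003,Synthetic stress probe C,Cellular stress,Hypoxia
X4004,Synthetic stress probe D,Cellular stress,Apoptosis
X4005,Synthetic stress probe E,Cellular stress,Membrane permeability
X4006,Synthetic stress probe F,Cellular stress,Proteasome activity
X4007,Synthetic stress probe G,Cellular stress,Lipid peroxidation
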