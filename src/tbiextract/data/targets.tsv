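intraparenchymal hemorrhage	INTRAPARENCHYMAL_HEMORRHAGE	(intra)?parenchymal\s+(hemorrhage|hematoma|blood)
facial fracture	FACIAL_FRACTURE	(facial|nasal|orbital|zygomatic|maxillary|mandibular)(\s+bone(s)?)?\s+fracture(s)?
extraaxial fluid collection	EXTRAAXIAL_FLUID_COLLECTION	extra-?axial\s+(fluid\s+)?collection(s)?
hypodensities	HYPODENSITIES	hypodensit(y|ies)|hypoattenuation(s)?|low\s+attenuation|hypodense\s+(area|region|focus|foci|lesion)(s)?
skull fracture	SKULL_FRACTURE	(skull|calvarial|cranial|occipital|parietal|temporal|frontal)(\s+bone(s)?)?\s+fracture(s)?
intraventricular hemorrhage	INTRAVENTRICULAR_HEMORRHAGE	intraventricular\s+(hemorrhage|hematoma|blood)
herniation	HERNIATION	herniation(s)?
mass effect	MASS_EFFECT	mass\s+effect
subarachnoid hemorrhage	SUBARACHNOID_HEMORRHAGE	subarachnoid\s+(hemorrhage|hematoma|blood)
subdural hemorrhage	SUBDURAL_HEMORRHAGE	subdural\s+(hemorrhage|hematoma|blood|collection)
hyperdensities	HYPERDENSITIES	hyperdensit(y|ies)|hyperattenuation(s)?|high\s+attenuation|hyperdense\s+(area|region|focus|foci|lesion)(s)?
atrophy	ATROPHY	atrophy|volume\s+loss
contusion	CONTUSION	contusion(s)?
hemorrhage nos	HEMORRHAGE_NOS	(intracranial\s+)?(hemorrhage(s)?|hematoma(s)?)
swelling	SWELLING	(brain\s+|cerebral\s+)?swelling|(brain|cerebral)\s+edema
pneumocephalus	PNEUMOCEPHALUS	pneumocephalus|intracranial\s+air
ischemia	ISCHEMIA	ischemia|ischemic\s+(change(s)?|infarct(s)?)|infarct(ion)?(s)?
epidural hemorrhage	EPIDURAL_HEMORRHAGE	epidural\s+(hemorrhage|hematoma|blood|collection)
anoxic	ANOXIC	anoxia|anoxic(\s+(brain\s+)?injury)?
aneurysm	ANEURYSM	aneurysm(s|al)?
hydrocephalus	HYDROCEPHALUS	hydrocephalus|ventriculomegaly
intracranial pathology	INTRACRANIAL_PATHOLOGY	intracranial\s+(pathology|abnormalit(y|ies)|process(es)?|finding(s)?)
gray-white differentiation	GRAY-WHITE_DIFFERENTIATION	gr[ae]y[\s-]?white\s+(matter\s+)?differentiation
cistern	CISTERN	cistern(s)?
midline shift	MIDLINE_SHIFT	midline\s+shift(ing)?|shift\s+of\s+(the\s+)?midline
diffuse axonal injury	DIFFUSE_AXONAL_INJURY	diffuse\s+axonal\s+injur(y|ies)|DAI
microhemorrhage	MICROHEMORRHAGE	micro-?hemorrhage(s)?|microbleed(s)?
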