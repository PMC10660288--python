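term	tissue_category	system_category
hippocampus	brain	nervous
cortex	brain	nervous
frontal cortex	brain	nervous
cerebellum	brain	nervous
dorsolateral prefrontal cortex	brain	nervous
astrocyte	brain	nervous
microglia	brain	nervous
neuron	brain	nervous
liver	liver	digestive
hepatocyte	liver	digestive
colon	intestine	digestive
small intestine	intestine	digestive
stomach	stomach	digestive
heart	heart	cardiovascular
left ventricle	heart	cardiovascular
aorta	blood vessel	cardiovascular
coronary artery	blood vessel	cardiovascular
whole blood	blood	immune
monocyte	blood	immune
t cell	blood	immune
b cell	blood	immune
macrophage	blood	immune
spleen	spleen	immune
lung	lung	respiratory
kidney	kidney	renal
pancreas	pancreas	endocrine
thyroid	thyroid	endocrine
adrenal gland	adrenal gland	endocrine
skeletal muscle	muscle	musculoskeletal
fibroblast	connective	musculoskeletal
adipose	adipose	metabolic
skin	skin	integumentary
testis	testis	reproductive
ovary	ovary	reproductive
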