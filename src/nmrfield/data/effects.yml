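# Default class-effect design for the synthetic cohort.
#
# Each entry is [class_a, class_b, metabolite, log2_fold_change]: the designed
# log2 change of the metabolite from class_a to class_b.  Signs encode the
# reported direction of each tissue-class comparison; magnitudes are free
# design defaults (|log2FC| = 1 for the strongest significance tier, 0.5 for
# the weaker tier) and can be overridden from user YAML.
#
# Tissue classes (1-9): 1 control normal squamous; 2 normal squamous in
# Barrett's patients; 3 normal squamous in EAC patients (pre-chemo);
# 4 Barrett's tissue in Barrett's patients; 5 Barrett's tissue in EAC patients
# (pre-chemo); 6 EAC tumour (pre-chemo); 7/8/9 post-chemo counterparts of
# 3/5(Barrett's)/6.
effects:
  # control normal vs EAC tumour
  - [1, 6, myoinositol, 1.0]
  - [1, 6, inosine, 1.0]
  - [1, 6, hypoxanthine, 1.0]
  - [1, 6, 3-hydroxybutyrate, 1.0]
  - [1, 6, glycerophosphocholine, 1.0]
  - [1, 6, phosphocholine, 1.0]
  - [1, 6, formate, 1.0]
  - [1, 6, glutamine, -1.0]
  - [1, 6, alanine, -1.0]
  - [1, 6, creatine, -1.0]
  - [1, 6, ADP, -1.0]
  - [1, 6, fumarate, -1.0]
  # field effect: control normal vs normal-in-EAC-patients
  - [1, 3, 3-hydroxybutyrate, 1.0]
  - [1, 3, succinate, 1.0]
  - [1, 3, formate, 1.0]
  - [1, 3, acetate, 0.5]
  - [1, 3, glycerophosphocholine, 0.5]
  - [1, 3, ADP, 0.5]
  - [1, 3, lactate, 0.5]
  # control normal vs normal-in-Barrett's-patients
  - [1, 2, formate, 0.5]
  - [1, 2, 3-hydroxybutyrate, -0.5]
  # normal-in-Barrett's vs normal-in-EAC-patients
  - [2, 3, 3-hydroxybutyrate, 0.5]
  # squamous-to-columnar shift (Barrett's patients)
  - [2, 4, 3-hydroxybutyrate, 1.0]
  - [2, 4, hypoxanthine, 1.0]
  - [2, 4, phosphocholine, 1.0]
  - [2, 4, glycerophosphocholine, 1.0]
  - [2, 4, glutamine, -1.0]
  - [2, 4, alanine, -1.0]
  # Barrett's tissue without vs with adjacent EAC
  - [4, 5, phosphocholine, 0.5]
  - [4, 5, leucine, -0.5]
  - [4, 5, isoleucine, -0.5]
  - [4, 5, valine, -0.5]
  # normal-in-EAC-patients vs EAC tumour (same signature as 1 vs 6, reduced)
  - [3, 6, myoinositol, 0.5]
  - [3, 6, inosine, 0.5]
  - [3, 6, hypoxanthine, 0.5]
  - [3, 6, 3-hydroxybutyrate, 0.5]
  - [3, 6, glycerophosphocholine, 0.5]
  - [3, 6, phosphocholine, 0.5]
  - [3, 6, formate, 0.5]
  - [3, 6, glutamine, -0.5]
  - [3, 6, alanine, -0.5]
  - [3, 6, creatine, -0.5]
  - [3, 6, ADP, -0.5]
  - [3, 6, fumarate, -0.5]
  # Barrett's tissue vs EAC tumour in EAC patients
  - [5, 6, glutamate, 0.5]
  - [5, 6, glycerophosphocholine, 0.5]
  - [5, 6, hypoxanthine, 0.5]
  - [5, 6, propionate, -0.5]
  - [5, 6, creatine, -0.5]
  # chemotherapy effect on tumour tissue
  - [6, 9, lactate, 1.0]
  - [6, 9, formate, -1.0]
  # chemotherapy effect on normal squamous tissue
  - [3, 7, valine, 1.0]
  - [3, 7, succinate, 1.0]
  - [3, 7, myoinositol, 1.0]
  - [3, 7, glycine, 1.0]
  - [3, 7, creatine, 1.0]
  - [3, 7, lactate, 1.0]
  - [3, 7, formate, -1.0]
  - [3, 7, aspartate, -1.0]
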