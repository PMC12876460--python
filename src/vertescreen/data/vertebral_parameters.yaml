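# Vertebral-column parameter catalogue for the IMPC release-19 screen.
#
# `parameters` lists the 25 retained vertebral parameters with their
# phenotyping-pipeline IDs, the six general vertebral categories, and the
# published per-parameter candidate-gene counts (reference values used by the
# reporting layer; the pipeline recomputes counts from data).
#
# `excluded` records skeletal parameters dropped from the screen, keyed by
# reason: no associated genes, ribcage, skull/teeth, appendicular skeleton,
# or body length.

parameters:
  IMPC_GEL_064_001: {name: "Somite Morphology",                category: "somitogenesis",        n_genes: 24}
  IMPC_XRY_057_001: {name: "Kyphosis",                         category: "spine shape",          n_genes: 7}
  IMPC_XRY_058_001: {name: "Lordosis",                         category: "spine shape",          n_genes: 1}
  IMPC_XRY_055_001: {name: "Shape of spine",                   category: "spine shape",          n_genes: 14}
  IMPC_GEP_078_001: {name: "Curl or short tail",               category: "tail morphology",      n_genes: 8}
  IMPC_CSD_002_001: {name: "Tail - length",                    category: "tail morphology",      n_genes: 12}
  IMPC_CSD_004_001: {name: "Tail - morphology (9wks)",         category: "tail morphology",      n_genes: 14}
  IMPC_CSD_003_001: {name: "Tail - thickness",                 category: "tail morphology",      n_genes: 6}
  IMPC_GEL_033_001: {name: "Tail bud morphology",              category: "tail morphology",      n_genes: 11}
  IMPC_GEM_029_001: {name: "Tail Morphology (E12.5)",          category: "tail morphology",      n_genes: 9}
  IMPC_GEO_033_001: {name: "Tail Morphology (E14.5-15.5)",     category: "tail morphology",      n_genes: 14}
  IMPC_GEP_038_001: {name: "Tail Morphology (E18.5)",          category: "tail morphology",      n_genes: 18}
  IMPC_XRY_019_001: {name: "Fusion of vertebrae",              category: "vertebral form",       n_genes: 30}
  IMPC_XRY_018_001: {name: "Shape of vertebrae",               category: "vertebral form",       n_genes: 19}
  IMPC_XRY_060_001: {name: "Transitional vertebrae",           category: "vertebral form",       n_genes: 15}
  IMPC_XRY_017_001: {name: "Number of caudal vertebrae",       category: "vertebral number",     n_genes: 17}
  IMPC_XRY_015_001: {name: "Number of lumbar vertebrae",       category: "vertebral number",     n_genes: 5}
  IMPC_XRY_016_001: {name: "Number of pelvic vertebrae",       category: "vertebral number",     n_genes: 4}
  IMPC_XRY_067_001: {name: "Caudal processes",                 category: "vertebral processes",  n_genes: 2}
  IMPC_XRY_063_001: {name: "Cervical processes",               category: "vertebral processes",  n_genes: 11}
  IMPC_XRY_061_001: {name: "Fusion of processes",              category: "vertebral processes",  n_genes: 11}
  IMPC_XRY_065_001: {name: "Lumbar processes",                 category: "vertebral processes",  n_genes: 2}
  IMPC_XRY_020_001: {name: "Processes on vertebrae",           category: "vertebral processes",  n_genes: 5}
  IMPC_XRY_066_001: {name: "Sacral processes",                 category: "vertebral processes",  n_genes: 2}
  IMPC_XRY_064_001: {name: "Thoracic processes",               category: "vertebral processes",  n_genes: 12}

excluded:
  no_genes:
    - "Caudal vertebrae morphology"
    - "Cervical vertebrae morphology"
    - "Fusion of ribs"
    - "Lumbar vertebrae morphology"
    - "Missing cranial rib"
    - "Number of cervical vertebrae"
    - "Number of thoracic vertebrae"
    - "Number of ribs (right)"
    - "Number of ribs (left)"
    - "Pelvic vertebrae morphology"
    - "Rib morphology"
    - "Scoliosis"
    - "Thoracic vertebrae morphology"
  ribcage:
    - "Shape of ribcage"
    - "Shape of ribs"
  skull_teeth:
    - "Branchial arch morphology"
    - "Craniofacial morphology"
    - "Mandibles"
    - "Maxilla/Pre-maxilla"
    - "Skull shape"
    - "Teeth"
    - "Teeth presence"
    - "Zygomatic bone"
  appendicular:
    - "Brachydactyly"
    - "Clavicle"
    - "Digit integrity"
    - "Femur"
    - "Fibula"
    - "Hindlimbs - size"
    - "Hindpaw - shape"
    - "Humerus"
    - "Joints"
    - "Limb Bud Morphology"
    - "Limb morphology"
    - "Limb Plate Morphology"
    - "Number of digits"
    - "Pelvis"
    - "Polysyndactylism"
    - "Radius"
    - "Scapulae"
    - "Syndactylism"
    - "Syndactyly"
    - "Tibia"
    - "Tibia length (long)"
    - "Tibia length (short)"
    - "Ulna"
  body_length:
    - "Body length"
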