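code,name,l2,l3
kyphosis,Excess convex sagittal spinal curvature,Spine,Shape
lordosis,Excess concave sagittal spinal curvature,Spine,Shape
scoliosis,Lateral (coronal) spinal curvature,Spine,Shape
spine-shape,General abnormal spine shape,Spine,Shape
spine-morphology,Abnormal spine morphology,Spine,Morphology
vertebral-morphology,Abnormal vertebral morphology,Spine,Morphology
vertebral-fusion,Fused vertebrae,Spine,Fusion
vertebral-displacement-cervical,Displaced cervical vertebrae,Spine,Cervical
vertebral-displacement-thoracic,Displaced thoracic vertebrae,Spine,Thoracic
vertebral-displacement-lumbar,Displaced lumbar vertebrae,Spine,Lumbar
cervical-anomaly,Cervical vertebral anomaly,Spine,Cervical
thoracic-anomaly,Thoracic vertebral anomaly,Spine,Thoracic
lumbar-anomaly,Lumbar vertebral anomaly,Spine,Lumbar
caudal-truncation,Truncated caudal vertebral series,Spine,Caudal
caudal-kink,Kinked tail,Spine,Caudal
caudal-deformation,Deformed caudal vertebrae,Spine,Caudal
vertebral-number,Abnormal number of vertebrae,Spine,Other
sacral-anomaly,Sacral vertebral anomaly,Spine,Other
spine-other,Other spinal abnormality,Spine,Other
rib-fusion,Fused ribs,Ribcage,Fusion
rib-number,Abnormal number of ribs,Ribcage,Other
rib-shape,Abnormal rib shape,Ribcage,Shape
rib-morphology,Abnormal rib morphology,Ribcage,Morphology
sternum-morphology,Abnormal sternum morphology,Ribcage,Morphology
costal-joint-anomaly,Costovertebral joint anomaly,Ribcage,Joints
rib-thickening,Thickened ribs,Ribcage,Morphology
ribcage-other,Other ribcage abnormality,Ribcage,Other
mandible-anomaly,Mandible abnormality,Skull,Morphology
maxilla-anomaly,Maxilla abnormality,Skull,Morphology
premaxilla-anomaly,Premaxilla abnormality,Skull,Morphology
skull-shape,Abnormal skull shape,Skull,Shape
teeth-anomaly,Tooth abnormality,Skull,Other
zygomatic-anomaly,Zygomatic bone abnormality,Skull,Morphology
cranial-fusion,Fused cranial sutures,Skull,Fusion
skull-morphology,Abnormal skull morphology,Skull,Morphology
skull-other,Other skull abnormality,Skull,Other
syndactylism,Fused digits,Limbs,Digits
polydactyly,Supernumerary digits,Limbs,Digits
digit-integrity,Compromised digit integrity,Limbs,Digits
femur-anomaly,Femur abnormality,Limbs,Other
fibula-anomaly,Fibula abnormality,Limbs,Other
humerus-anomaly,Humerus abnormality,Limbs,Other
tibia-anomaly,Tibia abnormality,Limbs,Other
ulna-anomaly,Ulna abnormality,Limbs,Other
limb-joint-anomaly,Limb joint abnormality,Limbs,Joints
joint-gap,Abnormal joint separation,Whole-body,Joints
joint-fusion,Fused joints,Whole-body,Joints
clavicle-anomaly,Clavicle abnormality,Whole-body,Other
scapula-anomaly,Scapula abnormality,Whole-body,Other
pelvis-anomaly,Pelvis abnormality,Whole-body,Other
pelvis-shape,Abnormal pelvis shape,Whole-body,Shape
wholebody-morphology,Whole-body skeletal morphology abnormality,Whole-body,Morphology
wholebody-other,Other whole-body abnormality,Whole-body,Other
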