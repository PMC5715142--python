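# Default disease-etiology mapping for pregnancy-induced hypertension (PIH).
# Each category lists the GO biological-process identifiers assigned to that
# disease mechanism. The assignment is editorial domain judgment, shipped as
# data so users can edit or replace it; a term may appear in at most one
# category. GO:0045766 (positive regulation of angiogenesis) is assigned to
# the placental/trophoblast ischemia category.
endothelial cell activation and injury:
  - GO:0007596   # blood coagulation
  - GO:0030168   # platelet activation
  - GO:0002576   # platelet degranulation
  - GO:0030195   # negative regulation of blood coagulation
  - GO:0010544   # negative regulation of platelet activation
  - GO:0007597   # blood coagulation, intrinsic pathway
  - GO:0072012   # glomerulus vasculature development
placental or trophoblast cell ischemia:
  - GO:0045429   # positive regulation of nitric oxide biosynthetic process
  - GO:0008217   # regulation of blood pressure
  - GO:0043066   # negative regulation of apoptotic process
  - GO:0001890   # placenta development
  - GO:0010595   # positive regulation of endothelial cell migration
  - GO:0042311   # vasodilation
  - GO:0007263   # nitric oxide mediated signal transduction
  - GO:0001525   # angiogenesis
  - GO:0051000   # positive regulation of nitric-oxide synthase activity
  - GO:0035924   # cellular response to vascular endothelial growth factor stimulus
  - GO:0048010   # vascular endothelial growth factor receptor signaling pathway
  - GO:0045766   # positive regulation of angiogenesis
  - GO:0001974   # blood vessel remodeling
hypoxia and oxidative stress:
  - GO:2000379   # positive regulation of reactive oxygen species metabolic process
  - GO:0071456   # cellular response to hypoxia
  - GO:0001666   # response to hypoxia
  - GO:0034097   # response to cytokine
  - GO:0019221   # cytokine-mediated signaling pathway
maternal-fetal immune tolerance disorders:
  - GO:0071356   # cellular response to tumor necrosis factor
  - GO:0001819   # positive regulation of cytokine production
  - GO:1902042   # negative regulation of extrinsic apoptotic signaling pathway via death domain receptors
  - GO:0032757   # positive regulation of interleukin-8 production
  - GO:0071347   # cellular response to interleukin-1
  - GO:0030217   # T cell differentiation
  - GO:0050852   # T cell receptor signaling pathway
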