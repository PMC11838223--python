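# Marker genes per cell type for the two-round reference-profile typing.
# round1: broad bone-marrow types; round2: lymphocyte subtypes (applied only
# to cells called T cell / B cell in round 1).
round1:
  erythroid progenitor: [HBB, HBA1]
  megakaryocyte: [PF4, PPBP]
  dendritic cell: [IL3RA]
  T cell: [CD3E, CD3D, CD3G]
  B cell: [CD19, CD79A]
  monocyte progenitor: [MPO, ELANE]
  CD14 monocyte: [CD14, CSF3R, S100A9]
  NK cell: [GNLY, NKG7]
  CD16 monocyte: [FCGR3A]
  stromal: [CXCL12, COL3A1]
round2:
  T CD4 naive: [CD4, IL7R, CCR7]
  T CD8: [CD8A, CD8B, GZMK, GZMH]
  B naive: [MS4A1, TCL1A]
  B plasma: [JCHAIN]
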