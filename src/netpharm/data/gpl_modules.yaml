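# Default therapeutic-module map for the gastric precancerous lesion (GPL)
# integrated pathway: nine key KEGG pathways assigned to the three modules
# (cell proliferation, cell apoptosis, mucosal inflammation). A pathway may
# carry several labels; retained pathways absent from this map are reported
# as unassigned, not errors.
vocabulary:
  - proliferation
  - apoptosis
  - inflammation
assignments:
  hsa05200: [proliferation, apoptosis, inflammation]  # pathways in cancer
  hsa04151: [proliferation]                           # PI3K-Akt signaling
  hsa04010: [proliferation, inflammation]             # MAPK signaling
  hsa04014: [apoptosis]                               # Ras signaling
  hsa04068: [apoptosis]                               # FoxO signaling
  hsa04066: [proliferation]                           # HIF-1 signaling
  hsa04668: [apoptosis, inflammation]                 # TNF signaling
  hsa04115: [apoptosis]                               # p53 signaling
  hsa04064: [inflammation]                            # NF-kappa B signaling
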