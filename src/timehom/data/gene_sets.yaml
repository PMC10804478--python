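# Default marker-gene sets mapping each immune feature of the panel to the
# genes whose average normalized expression estimates its abundance in bulk
# RNA-seq.  User-overridable; the TLS signature uses the canonical
# lymphoid-neogenesis chemokines.
CD4: [CD4]
CD8: [CD8A, CD8B]
Foxp3: [FOXP3]
CD20: [MS4A1]
CD68: [CD68]
LAMP3: [LAMP3]
PD-1: [PDCD1]
PD-L1: [CD274]
TLS: [CCL19, CCL21, CXCL13]
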