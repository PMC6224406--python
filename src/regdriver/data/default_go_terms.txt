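# Default term list for interaction-level enrichment scans: pathway and
# hallmark processes recurrently disrupted in plasma-cell malignancies.
# One term per line; replace with project-specific GO identifiers/names.
cell adhesion
inflammatory response
NIK/NF-kB signaling
MAPK signaling
regulation of B-cell activation
B-cell activation
B-cell differentiation
B-cell proliferation
cytokine signaling
apoptotic process
DNA damage response
cell cycle regulation
angiogenesis
immune effector process
chromatin remodeling
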