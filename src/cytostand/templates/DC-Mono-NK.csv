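alias,parent,dims,method,args,signs,denominator,report
Lin-,root,Lin,density_cut,,-,,0
Lin-/CD14+,Lin-,CD14,density_cut,,+,,1
Lin-CD14-,Lin-,CD14,density_cut,,-,,1
CD14+/CD16+,Lin-,CD14|CD16,quadrant,,++,,1
HLADR+,Lin-CD14-,HLA-DR,density_cut,,+,,1
HLADR-,Lin-CD14-,HLA-DR,density_cut,,-,,0
CD11c+/CD123-,HLADR+,CD11c|CD123,quadrant,,+-,,1
CD11c-/CD123+,HLADR+,CD11c|CD123,quadrant,,-+,,1
CD11c+/CD123+,HLADR+,CD11c|CD123,quadrant,,++,,1
CD11c-/CD123-,HLADR+,CD11c|CD123,quadrant,,--,,1
CD16+/CD56+,HLADR-,CD16|CD56,quadrant,,++,,1
CD16-/CD56+,HLADR-,CD16|CD56,quadrant,,-+,,1
CD16+/CD56-,HLADR-,CD16|CD56,quadrant,,+-,,1
CD16-/CD56-,HLADR-,CD16|CD56,quadrant,,--,,1
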