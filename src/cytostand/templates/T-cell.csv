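alias,parent,dims,method,args,signs,denominator,report
CD3,root,CD3,density_cut,,+,,0
CD4,CD3,CD4|CD8,quadrant,,+-,,0
CD8,CD3,CD4|CD8,quadrant,,-+,,0
CD4 Activated,CD4,CD38|HLA-DR,quadrant,,++,CD4,1
CD8 Activated,CD8,CD38|HLA-DR,quadrant,,++,CD8,1
CD4 Naive,CD4,CCR7|CD45RA,quadrant,,++,CD4,1
CD4 Central Memory,CD4,CCR7|CD45RA,quadrant,,+-,CD4,1
CD4 Effector,CD4,CCR7|CD45RA,quadrant,,-+,CD4,1
CD4 Effector Memory,CD4,CCR7|CD45RA,quadrant,,--,CD4,1
CD8 Naive,CD8,CCR7|CD45RA,quadrant,,++,CD8,1
CD8 Central Memory,CD8,CCR7|CD45RA,quadrant,,+-,CD8,1
CD8 Effector,CD8,CCR7|CD45RA,quadrant,,-+,CD8,1
CD8 Effector Memory,CD8,CCR7|CD45RA,quadrant,,--,CD8,1
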