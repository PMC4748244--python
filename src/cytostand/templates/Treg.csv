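alias,parent,dims,method,args,signs,denominator,report
CD3,root,CD3,density_cut,,+,,0
Total CD4,CD3,CD4,density_cut,,+,,1
LoCD127/HiCD25,Total CD4,CD127|CD25,rectangle,,-+,,1
Total T-regulatory,LoCD127/HiCD25,CCR4,density_cut,,+,Total CD4,1
Memory T-regulatory,Total T-regulatory,CD45RO,density_cut,,+,Total T-regulatory,1
Naive T-regulatory,Total T-regulatory,CD45RO,density_cut,,-,Total T-regulatory,1
Activated,Total T-regulatory,HLA-DR,density_cut,,+,Total T-regulatory,1
CCR4-/CD45RO-,LoCD127/HiCD25,CCR4|CD45RO,quadrant,,--,,1
CCR4-CD45RO+,LoCD127/HiCD25,CCR4|CD45RO,quadrant,,-+,,1
CCR4+/CD45RO-,LoCD127/HiCD25,CCR4|CD45RO,quadrant,,+-,,1
CCR4-HLADR-,LoCD127/HiCD25,CCR4|HLA-DR,quadrant,,--,,1
CCR4-/HLADR+,LoCD127/HiCD25,CCR4|HLA-DR,quadrant,,-+,,1
CCR4+/HLADR+,LoCD127/HiCD25,CCR4|HLA-DR,quadrant,,++,,1
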