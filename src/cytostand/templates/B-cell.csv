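alias,parent,dims,method,args,signs,denominator,report
CD3-,root,CD3,density_cut,,-,,0
CD19,CD3-,CD19,density_cut,,+,root,1
CD20,CD3-,CD20,density_cut,,+,root,1
B20,CD19,CD20,density_cut,,+,,0
B20-,CD19,CD20,density_cut,,-,,0
Naive B,B20,IgD|CD27,quadrant,,+-,,1
Memory IgD+,B20,IgD|CD27,quadrant,,++,,1
Memory IgD-,B20,IgD|CD27,quadrant,,-+,,1
IgD-/CD27-,B20,IgD|CD27,quadrant,,--,,1
Transitional,B20,CD24|CD38,tail,k=3,++,,1
Plasmablasts,B20-,CD24|CD38,tail,k=3,++,,1
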