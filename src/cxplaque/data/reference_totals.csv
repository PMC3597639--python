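combination,compartment,total_3mo,total_22mo,printed_percent,printed_decimals
Cx26,parenchymal,924662.2,437637.8,-52,0
Cx26,vascular,74374.1,32935.5,-55,0
Cx30,parenchymal,592002.0,4355278.7,636,0
Cx30,vascular,98788.3,654464.4,562,0
Cx43,parenchymal,428717.9,1185838.8,176,0
Cx43,vascular,60393.7,58757.8,-2,0
Cx45,parenchymal,267653.5,758149.4,183,0
Cx45,vascular,10821.6,14634.7,35,0
Cx26/Cx30,parenchymal,11168.9,8912.0,-20,0
Cx26/Cx30,vascular,22540.9,12288.1,-45,0
Cx26/Cx43,parenchymal,9988.3,7409.4,-25,0
Cx26/Cx43,vascular,28875.2,12879.0,-55,0
Cx26/Cx45,parenchymal,16387.4,42487.8,159,0
Cx26/Cx45,vascular,21548.9,58597.5,171,0
Cx30/Cx43,parenchymal,3471.1,6114.1,76,0
Cx30/Cx43,vascular,7105.6,10188.1,71,0
Cx30/Cx45,parenchymal,2526.5,13212.6,422,0
Cx30/Cx45,vascular,5153.2,12694.2,146,0
Cx43/Cx45,parenchymal,6776.9,7202.2,6.3,1
Cx43/Cx45,vascular,11896.1,11155.5,-6.2,1
Cx26/Cx30/Cx43,parenchymal,2550.2,4391.5,72,0
Cx26/Cx30/Cx43,vascular,5444.8,9419.1,72,0
Cx26/Cx30/Cx45,parenchymal,1700.1,8860.2,421,0
Cx26/Cx30/Cx45,vascular,2767.3,10576.9,282,0
Cx26/Cx43/Cx45,parenchymal,4746.2,8083.0,70,0
Cx26/Cx43/Cx45,vascular,10777.8,11587.3,7.5,1
Cx30/Cx43/Cx45,parenchymal,1558.4,5181.4,232,0
Cx30/Cx43/Cx45,vascular,2209.7,9149.3,314,0
Cx26/Cx30/Cx43/Cx45,parenchymal,1487.6,5181.4,248,0
Cx26/Cx30/Cx43/Cx45,vascular,2637.3,9452.2,258,0
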