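item,subscale,no_brace,emg_myopro,bci_myopro
Block 10 cm^3,grasp,0,0,0
Block 2.5 cm^3,grasp,0,1,1
Block 5 cm^3,grasp,0,0,1
Block 7.5 cm^3,grasp,0,0,0
Cricket ball,grasp,0,0,0
Sharpening stone,grasp,0,1,1
Pour water from one glass to another,grip,0,0,0
Displace 2.25-cm alloy tube from one side of table to the other,grip,0,1,1
Displace 1-cm alloy tube from one side of table to other,grip,0,1,1
Put washer over bolt,grip,0,1,1
Ball bearing held between ring finger and thumb,pinch,0,0,0
Marble held between index finger and thumb,pinch,0,0,1
Ball bearing held between middle finger and thumb,pinch,0,0,0
Ball bearing held between index finger and thumb,pinch,0,0,0
Marble held between ring finger and thumb,pinch,0,0,0
Marble held between middle finger and thumb,pinch,0,0,0
Hand to behind the head,gross,0,0,0
Hand to top of head,gross,0,0,0
Hand to mouth,gross,0,0,3
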