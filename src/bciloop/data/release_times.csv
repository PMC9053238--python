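condition,seconds
BCI,3
BCI,4
BCI,1
BCI,1
BCI,2
BCI,6
BCI,1
BCI,8
BCI,5
BCI,1
BCI,7
BCI,18
BCI,13
BCI,7
BCI,26
BCI,24
BCI,2
BCI,3
BCI,2
BCI,3
BCI,1
BCI,2
BCI,5
BCI,2
BCI,9
BCI,4
BCI,2
BCI,5
BCI,9
BCI,14
BCI,7
BCI,4
BCI,12
EMG,45
EMG,8
EMG,13
EMG,24
EMG,5
EMG,1
EMG,7
EMG,19
EMG,3
EMG,4
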