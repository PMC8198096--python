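quantity,Fluorouracil,Leucovorin,Irinotecan
median,770,725,300
min,598,75,208
number_of_cycles,12,12,12
cycle_length,14,14,14
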