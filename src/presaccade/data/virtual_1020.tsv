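FrontalZ	5,12,11,16,19,10
CentralZ	7,107,32,81,55
ParietalZ	61,68,73,79
OccipitalZ	72,77,76
FrontalPole1	22,23,18
FrontalPole2	14,15,9
Frontal3	25,20,21,24
Frontal4	124,119,4,3
Frontal7	34,28,35
Frontal8	122,123,117
Central3	30,31,36,37,42,43
Central4	94,104,105,106,111,112
Temporal3	40,41,46,47
Temporal4	103,109,110,116
Temporal5	51,58,59,64,65,50
Temporal6	91,92,96,97,98,102
Parietal3	52,53,54,60
Parietal4	80,86,87,93
Occipital1	66,70,71
Occipital2	85,84,90
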