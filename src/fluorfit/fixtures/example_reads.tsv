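4
1
5
4669.092089220822	6555.513812632339	-696.1472143284508	-621.6209701857367
7014.018463543436	4441.52477790367	324.5814666329988	-722.8045447126433
6113.464868098895	8027.404973971755	221.07013640404548	-145.3918033523877
5829.7044684471575	5822.97403870781	5556.225651855738	4586.634694553171
5274.698054248857	7180.9854650319985	763.3932315403257	393.39997655557585
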