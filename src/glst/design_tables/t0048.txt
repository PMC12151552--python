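# t=48 symmetry=ico m_hemisphere=1560
0.49791815590943284 4.0853442851335204
1.6982833950949741 2.5789578150316324
2.4027010087017304 5.1981109069848817
2.7921133629472017 2.4951841379875508
1.509136617578116 3.5157926471287184
0.68163253596217632 5.5775712761198397
0.76557677140485458 1.1260155659225137
2.3126197858803552 2.2015350241884639
1.3869793134571411 2.7183650087836391
0.93711816486290722 4.4199586714169694
2.5551803024886861 1.4500698846446305
0.73476292462396209 1.5421202447101423
1.4262208056070225 4.5400963754881944
1.4466869098793018 5.1981778198981559
1.7922913072515747 2.3239921580680964
1.1403342589875389 1.016838019923691
0.93041038190469039 0.66748863747278986
1.2211610386646998 3.4586200803379108
0.97308750182380488 5.102965870800924
2.0862761910357372 4.8355787622320685
0.81584461327281943 0.73884495689001062
2.6802883005972147 5.2018076681890362
1.9221839619373833 3.5269853173597339
1.7607387552429246 4.2437210053101335
1.3373113062897626 5.3546318815680385
1.8318031062484428 0.51680873045422049
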