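# t=106 symmetry=ico m_hemisphere=5340
2.4660729550323093 4.1264113483156724
0.39118965987636573 0.3672283556424506
0.94386292891887591 0.66124668134253872
2.0661840992774096 3.4255157546628854
0.62621444566429563 1.6639510690764641
0.95856497679078756 5.679623143435621
2.4511930331561769 4.6857841503817568
1.295985464064155 2.9526803553540613
1.9545050124616887 3.311213049967924
0.54753360742548884 0.16221550144452127
0.94456187326123531 3.892055709767011
2.7016642772915183 0.47462752518351059
2.5708402184536308 4.5605287741495015
0.85183952353576298 1.8832521422578814
1.3743133525490421 1.7271130929259471
1.2327624473614978 0.64315283836014481
1.2179811738847865 2.1959942205472811
2.4392344089251576 5.4995375348875388
2.257733334541268 1.2991734790654166
2.521329021083992 4.5428737490040376
2.1829641098159551 5.8276006470582713
2.2727399993192821 4.6719715088273182
1.1652710925678798 4.6058661163255126
1.2086680523491784 5.5880878756934136
1.7187864900099044 2.4952137456593628
1.4350527526455188 1.0386465984078233
1.3344173674487902 0.46673331625722408
1.8242103449107077 5.1399524047171692
1.5033439404753519 2.6432359236546326
2.6048051161264003 2.1838186752587943
2.1763486409722366 1.4206433774872309
2.0497666060159969 5.1995773626908495
2.6814475914528253 5.41619013476258
1.1255148943372477 5.7989361391692755
1.8775131257400501 1.7492861647094569
0.9203952347534009 0.86488460413745782
0.29923514750168229 4.6902667872292776
0.5929034391056609 5.7113321903415919
0.83503667738386422 0.12246221349264316
1.405453464972555 2.1315974323010161
0.94899683874258089 5.3434182597642792
2.1931314665406267 1.8400560228735723
2.5756362173109535 1.502257132557739
1.668127748921427 -0.059455604032550902
0.87581210329312809 2.8763836309997379
1.379630409473195 5.270470205489584
1.2079870552405003 2.3266519560805081
1.8129829410931082 2.2433197034436856
1.1146688001011189 1.1581720433901745
1.1542663656704997 5.3680554452081219
2.5955054690864676 2.8371973916452435
1.1599955792924328 2.4722199691775053
0.82542153432731413 1.5829810621900609
1.1733844263029847 6.265486470740778
2.2971751537846092 3.4753443865421914
2.4197541881163191 6.053690154799872
2.2888295920377146 3.5627493221228819
2.731035406968918 2.1582216907338156
1.9497032529873379 1.5078085491203548
1.7668386906702722 1.5791377257819945
1.9437217285807482 0.50912089440423502
2.4307971068241683 5.8850007608087145
2.1291240460019565 1.4319926470739319
0.91008681139860848 5.8407666241463012
1.8558922325543847 4.6674361833811107
1.4061285625683864 2.1924224397160672
1.3201888913852651 4.8619805337784268
1.0213438009997027 0.37641837490204638
2.6179206472069891 3.9143484323039321
0.65130210871159433 2.2159527949605873
0.45555035361298607 4.1324876391585468
0.70565411134118972 5.3678563047611192
0.50943495589250531 2.7586329005524894
2.0425652684800975 4.579935785936069
0.89833006992712028 6.0014340888691997
1.6333482217635003 5.0537964398805961
1.0841094400883617 4.6669137664449201
0.68763415121219307 3.410562649136534
1.6829560607935909 5.0789515085065879
0.58656663628228911 3.1194445097865664
2.8941967923296037 1.417007892263751
2.0420003793193797 2.9296206075198121
2.3772803301687069 5.4352067174754497
1.5144612926279848 2.9484922922090164
1.4729966213200463 1.709390044654898
1.5966563180302473 4.6932051066522495
2.1541500682512549 4.856826343072
0.69792915598643723 2.561065451046332
2.0803086971433737 1.3123575562547323
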