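# t=158 symmetry=ico m_hemisphere=11940
2.4931842648443991 4.6223809635574939
0.50033561282422934 1.5900891974870095
1.8317058652395954 1.4104313599738614
1.6046426169172618 2.4768756876109266
2.6340335510370179 3.2379376985757
1.6855864631346071 3.6585567834462629
2.8664778268712765 3.7102327042268217
1.2658800279655229 5.5912913512512121
0.7968241371818614 1.3676388648339863
0.85242791543626395 4.2473936697490178
2.1995428022101722 5.3056808801273503
0.29801847775737866 1.7672491725426591
3.0990145494415557 3.8807913621539649
1.8410694719745475 2.2119370400562688
0.93629150228837366 3.9232005156875371
2.0982415001779651 4.3180249704601215
1.992632092663577 2.6233969551911769
1.5363711263037589 4.4866110387242939
1.8180851973401249 3.7479745921496925
1.0078314830760748 4.9776669043943951
1.1796829971231939 0.87723481199541586
0.75101930052783095 3.7082114270201187
1.3369810630383865 0.67439340357805888
2.0431711254335148 1.30456180976731
2.854945852859065 5.6891803843784521
0.64981426365202433 3.1787564088229026
1.5387695514140951 2.9802438513811742
2.4087610272963116 4.9271077230557712
1.9739539232975145 0.64678654591435059
2.0944547107235092 1.7076254142443286
1.1791162910904227 5.1031142311606512
2.700979001954531 5.4778909110472354
1.1789355946144073 3.6546729057063261
2.2890365586263157 2.6358007563283028
1.5692082852689704 2.9635556801209191
2.0195235211917431 1.5462133159399358
0.78278358169279172 3.5144160731634746
0.067230738255511624 5.8739063121337631
2.1375875979142966 5.1715530598766843
2.7440601493641568 0.49994668779513834
2.502858902247532 1.6000961703859791
1.68691353809999 4.3799070747718494
1.7137295490203572 5.3338179702335928
2.3857169703145154 3.5763863144561787
1.436731436493587 5.5320334405159794
1.0313305000880091 2.4759016776378426
1.7051602842625773 0.31756542743318372
0.89216447772900376 2.7426526941334477
2.1575984544375255 1.9072036630249141
1.6259922817224655 2.735539685676851
1.4953056386190593 4.1737330383108038
1.1016326564032748 4.1706888132302389
1.4587970900419205 5.4874480894345883
2.8010434957843708 5.1391693431780539
2.2514827432031899 0.98013522425617228
1.3938861739315958 5.1994091560293381
1.2959067533897619 0.89882453295191089
1.649943960663542 0.88495277373891512
1.0890721464988817 4.1870997403997698
1.3014897999767834 1.5247004709866148
1.5914459320414294 1.2302447563432026
1.1184526876137451 2.3224611059270699
1.6855738509213065 5.5366866840142235
1.426508468090752 1.2174749798175513
1.629867961006962 5.0448285445940071
2.0953052090463622 0.71165305647915023
1.8535730059772559 2.0204230509829033
1.5219163614589075 6.2069651738291052
1.1219204842059889 5.2537548224830912
1.3680758997638904 1.7668967026270059
0.96600222677816272 1.0103648541127817
0.45719138538718923 0.51810347846442961
1.3257334380165033 0.88261127927129612
1.833219187680037 1.7672361700184409
2.2459087009792897 2.7944428218187065
1.0674489121477757 3.6778427134242579
1.9633201172264925 5.9033051248937092
2.3093954571493733 0.70302076090279697
1.888428619905496 5.928912381958896
2.3889389637390921 3.981861845468043
1.2652561940197722 4.3182481973558735
1.9441019447960997 3.3989397615890193
0.13714630078395215 0.73218353888617027
1.1643953985337645 4.7306727637705288
1.7168078760870857 1.7761194182592548
1.5611397543302359 3.5615222859573419
2.6544095572723614 3.7899679807163382
1.2058157986467508 0.45903656397666753
1.2628430325783762 0.285885120891267
2.186903039958072 1.7233572292132733
2.5096114942364385 2.4847821952548639
1.6226239526757331 5.0495210004723186
1.9655443115476401 2.3421939497924988
2.0459849517586579 0.9023904095787183
1.7801208819779546 1.5004247070663603
0.74108861904817225 3.3513984434477986
2.7597379051487132 4.6623935068391766
1.0397585528570623 2.3279035767063547
2.4628282530908447 3.7431458786504788
2.2618657248269161 5.562478519955576
1.673698644909166 5.1232906618782446
1.9276867042069139 0.38951061920968266
2.5844222530915486 4.6639614888232463
0.46697673760081349 3.8288654318855024
1.0289163647176143 4.6353553785707637
1.7234789932336287 2.778801736780836
0.62406491868205671 3.8856903992772494
1.5796265581593065 0.14544014062761004
1.2074315447630168 3.1020898377331139
1.4142712380890401 1.8487947547414794
1.4297207835659269 2.5947242937965189
1.7401573551388949 2.1168304695816156
2.6683562786968582 5.4849055542645226
1.0494492403326181 0.55326521933410311
1.4408056247372987 0.16608085750704493
2.3370197648298197 4.7484038733012994
0.91920001185881117 0.10869322289788637
0.88331970912331903 2.2447310639144264
1.404197660556026 3.1253127455860015
1.7345725292114522 5.4714519758372067
1.1539591797397377 5.320151534402223
1.723418978999635 2.1309526219054913
0.43902904004020488 0.6487071856907296
2.304928986523147 2.2200001599543073
2.6330316111451948 1.4889775253340387
1.7156866080193376 5.2536218765802696
1.1715179428181541 2.9453010990619157
2.4111898151816304 3.7197388378537299
0.67188672974280872 2.1230558857541433
1.8023758275187578 2.9104550299924625
1.2758957741477341 2.4099981361533671
1.6478892122432214 4.8200088069489206
1.2661423664547491 3.7455979708659441
1.303132442590605 -0.033854125204846368
1.2001664213208219 4.866118080959934
1.3744341208917472 2.3729761573734045
1.4452887746471714 3.8404295615884334
0.75026984725640111 3.7738050480999314
0.89293259602296493 4.8385303297945317
1.3043998939195895 4.4232535136286106
0.47271416913551761 5.073215662527601
1.7355278631567943 2.2099552906308331
0.55989867956111961 0.55587046272226515
1.0338047130968944 0.30490562460744891
1.6554591226396498 3.8429534719759637
2.1359698976914308 2.6031369152152384
1.8775201718371659 0.33184072418386557
2.2692889062267909 5.9417481575232953
1.3852316996042198 0.69265178197560406
1.3620449081229207 4.4404328652615908
2.3035668473106381 1.6511219444430267
1.6039335373184727 0.59025755823817216
1.9952248216398543 4.9664240563450557
2.3104177427853685 4.2665930152716856
0.92039109954901221 1.9179653539306718
2.3868649900644434 5.9937671558840497
2.6541280274305694 3.3932620566104674
1.6363543407888013 4.2377809310130869
1.5315336014757079 4.0440776949159378
1.8672206754966236 4.8231423989963131
1.5202713811924715 5.0152657434939547
0.62832302111501892 1.2078517683972121
2.1630200421346468 2.6681808908630966
1.6062882485313705 5.4821660098196512
1.4682851203008591 2.4200895425251843
0.83612075680439257 3.9616638407289106
2.7372282625380202 5.5574341187852951
2.5018398725945881 0.26966935518183816
1.6396290218997187 6.1886911731654335
1.5146681717065245 4.2753052269320815
0.5258011687035784 3.4490505070530602
2.2784264262349914 0.68509580860626473
1.1450476931108231 4.7614550778345235
0.64393955996554708 3.6704232688075829
2.7099866466367448 5.1782149982173715
2.1635223171602718 1.6370529346491871
1.4958475242207432 4.9484017963649638
2.5201325000389962 4.5787397583247973
2.2495071950294796 1.7274686780688286
1.380553920935818 4.4203213465398612
1.3014658943972632 4.7921278017367017
1.7110905847750499 1.6256224390511695
2.536250357733473 2.4151776190575629
2.9361129753012327 1.9042072091657012
1.7773757617116086 3.1137714635587477
0.25953667904994676 0.83969717602376048
2.7709022042973266 6.0426038632992878
1.6234755435042196 2.9572131447532155
2.1438607215463104 0.9686681566809261
1.6102224473109761 5.4435816987527703
0.68604597909931164 4.9882253793258844
0.90473252074740873 2.7004661344799814
1.2716160160122525 5.4059456618062525
1.5557587038357152 0.32091188738292376
1.1233793891574018 6.1860480126708497
2.3016517218057913 0.20103734368506651
1.3463675893741183 5.4257563127602682
1.1936137322782199 3.0127681959628063
0.88409126347870659 4.3554128680615225
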