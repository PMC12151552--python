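# t=130 symmetry=ico m_hemisphere=8100
0.99551591825353947 5.9173385460699466
1.5778358873941285 3.9858114233092863
2.3207427063544932 0.19050654631973948
1.0168616011558393 3.3311350452360515
0.60927087863356555 4.8015257145470889
1.5050729022851697 5.0007712733088896
2.7017614996825627 4.1551036485943653
1.3888274108071217 6.1152137731928145
0.70729910887308589 2.0985125999400025
1.7005356019483562 3.6497854663006217
1.8239207107009405 1.4763823020811579
1.0206995071306819 0.26657865246143087
1.9252606646330379 1.6340466088612298
0.34085169750062722 2.1599982305553245
0.88910209557111253 3.9714509840297891
2.1569475911831812 0.47880642054731265
1.897721188906111 1.1700162155917353
0.71482872210513082 1.0109365289127374
1.0906038296701954 5.8715224233929861
2.113402150974891 4.9381635913019322
1.3806046876227414 3.1255788660494703
1.8473781081668879 0.43542827103494125
1.4023637911662119 3.4666335943621589
1.0789670158988474 3.1689356865561682
1.2967258484532072 5.1048797048623271
1.244549591033868 2.142699332327648
1.0396028286579626 4.5306076740398744
1.3236547173727229 0.66077528838959287
0.29207293527115374 3.5548982291370237
2.2349932513349255 1.1620195820037189
1.7412326005313445 4.2708034639781296
1.4146187103060759 4.4941801426626391
2.2934853149050229 3.5575656935761488
1.2711995748686791 3.8756898773156405
0.55185558297292159 3.6585397045641161
2.0444858186642589 6.1234297663982238
1.9202789225602701 0.63993599327822293
1.2248285826154535 2.3340972630310066
2.6486257090070162 3.5436958893389146
1.1169379151220955 4.9847312849815584
2.4912511569604154 0.76841302614155094
1.8771937503124669 3.6175468122942491
2.4612093450634807 3.6633214354236792
2.0705552188048073 4.5132588213851736
1.0564742322722154 0.94424601014325071
2.3112553449447133 5.6259968309611432
1.9058319017610106 1.3118092339357605
0.41774787885698306 5.2057816842686178
1.2437191499590936 6.1529672043654253
1.0394873592233171 4.8216310566793288
1.5932904840103745 1.2165444874737024
2.4954621643668946 4.5892549711882067
1.3389177759498461 0.48873717239685266
1.3617862636713591 2.9227612050174234
1.2178551233924735 3.5516613570374962
1.3707389647789472 3.9305568999869962
2.2330764798144269 1.322147166631451
1.6788292953726722 2.3404779323461367
0.99222447528347679 4.0817228355457491
1.9366035432609183 6.1762702112174335
1.4966368252563351 0.69968895494930816
0.2596891670999627 4.4056758790003858
0.41477149776695321 2.4856176203229099
2.0655981957059355 0.92702067828365609
2.0717762373584891 3.978957368068762
1.3184615635498134 2.245824971010391
1.4229928863376398 0.44151476742466733
1.8017346285404203 4.549126812485234
1.937339709494263 1.2661517873054451
1.6004442042580471 5.2757965933750439
2.2394749277027901 2.092357233846192
1.8409079550318055 5.479788047515326
2.4659474783266555 2.9743940332301051
1.8116352145807197 5.2482670153402022
0.64496706728764619 2.9411587774578258
0.75186380108118112 5.2399698248306636
0.39569063825316386 4.9091437342952444
1.4160628721937845 5.2143133833548685
2.5770583510851472 1.0733862422448981
1.0398430845920197 1.8925110652922812
1.1769285095456778 3.2918326800996733
0.9898866556713406 2.4923050997502934
0.80770596059200406 0.78855106965524657
0.78138143175981933 5.7586644908732021
2.7516473982629197 3.1398206681941097
2.4812716861824828 4.3343952632261793
0.82238906687990454 4.1014668092504154
2.6596117724652522 0.52547958375899806
0.97167205300463833 1.8542632726707182
1.6697906745472737 5.8787998828573311
1.4033369958684601 3.8688465026003356
0.7087605638385841 6.2223908254101845
1.130201445995908 3.4397402299065458
1.6884834847705488 4.2462618856188881
1.5230058994019278 5.377164065786376
1.2673246941935439 5.9386520832979084
1.0180522900621669 1.9917381008966952
3.0489739789246006 1.7785700063012704
2.104373496448936 5.524902882686809
1.3142121467126915 2.7588710955563451
2.1367627850541502 1.6350416141883544
1.2396885531071056 4.9285351213741091
0.94732768435085479 5.7721175552731943
2.281430881020003 3.3186656753688113
0.52595361442121058 6.016678772419632
2.0392609287028827 0.87365812193898174
2.2754328092587417 2.3010223889044683
0.96647213539168453 4.1542543540602512
1.630010367537263 4.791323070703287
0.53373640625328012 3.5233239427165222
0.69177325555767866 2.0012966509122996
1.9313452940244498 5.073086580933194
0.5701330503057096 0.82133355679021947
1.0673103048562445 4.3469560381933476
1.2285404209688213 4.4191157376482062
0.71066854169497828 4.4006225965796304
0.57156488181027998 4.3498930954948003
1.5238909727859125 1.6897397118363282
2.1613805058312909 0.15510431796486063
1.6748365728698917 2.9772647349008277
2.6481661966876828 1.4329160399205958
1.0336538124588801 5.9458233816679975
1.1204975292549637 3.1933792595867718
0.48182749293167487 2.2699302912157546
2.3151797140745498 3.420209428152666
1.7964527506465202 3.1309717595535562
1.2607378482530349 1.3402716653694804
0.8902771351281038 3.5502126632577569
1.5080315094050383 -0.00026465997101040711
2.1538695356215074 5.4064022605054065
0.38529516979783623 0.11777409341581736
0.74547107544761426 5.3345629002378034
1.9497522380422367 5.2189630034076089
0.88985365455169085 2.4775657409922194
2.1271824042347296 0.92402051411625874
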