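# t=88 symmetry=ico m_hemisphere=3720
2.0992675556856475 5.2469536920354445
0.54347285678048141 0.81434435554267071
0.85128844294231032 0.13293917903179445
-0.030548846826990387 3.971022990535658
2.0465126472765669 4.1557882661559145
1.1688906270572537 1.5676103317412409
1.8656187799366111 3.1653966726449139
1.5197447763941689 3.409450125075324
1.0963601514202894 1.6789560079464945
1.7747123581840039 6.3157616532255174
0.63751415144739909 5.9616140183366984
2.7752149038151859 5.5864265464999923
0.68086548164647609 0.53447540056710319
0.82059790141237032 3.02671353633608
2.0738559470323175 5.321682569056466
1.1887509102383518 5.4761493147815479
0.32009642538732169 0.78901201215876449
1.1879028190921102 0.062591002076445065
1.2545479864049951 4.5852531713482554
1.9213430514361975 2.7704606280023749
1.4734156064247008 1.0266411925109051
0.42957772099614921 6.2137294398491383
2.4657430160814195 4.3951424833221315
2.4962258770931549 0.8782591596061381
2.1610384920640349 3.108190946804863
1.3941837366268488 5.7402374583156845
1.0841146326336217 0.52677220042327411
2.2940526831354711 0.45519457654015322
1.8470230913601229 2.7930232419723251
0.61075515955962922 1.4043222564507016
0.39456346660714281 5.1888117706271055
0.8105594193615594 2.829225435403536
0.6432216813887508 3.2181904126379139
1.0740489940929097 4.9821595943572632
2.0190108243583853 1.2722370204814308
2.4585645983428157 1.4454640376318042
0.92352517838500425 2.8520034642611924
1.2726159774458528 3.9537769840233472
1.494372888512745 2.730449805050108
2.1621715194484841 2.7467544002110733
1.1386211037373277 2.2788039745708328
0.095165962880616281 2.2835850550997794
2.6920851102938466 2.8216929743956891
1.1812802265216782 4.3768397428091301
1.0252986253585354 4.7571363766450476
0.46626944407115206 3.9820898574480807
1.8368748900794394 3.7672461182669572
0.54875332954651601 0.9764469111854357
0.95166202621816742 3.3503914725781105
0.84909889355491597 3.4563864482894702
1.4839771586571076 5.5593508292050791
2.4358307131752794 3.1714144076554209
2.4603518506487911 5.9170274347721836
1.3956197380365365 3.980013731044274
0.84487520895805746 0.845398744705533
1.4274327340360711 4.1423775998746519
1.278502087845359 5.4374648078194223
1.722753908046329 1.5575986452551911
0.8069426142807774 4.6059283578918171
2.1264237763459928 4.8171949259089528
1.9076088982916064 4.8917090755645534
1.1244992347102853 0.70968594564298726
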