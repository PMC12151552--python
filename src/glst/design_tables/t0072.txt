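# t=72 symmetry=ico m_hemisphere=2760
2.2590634580698348 6.114171530030033
0.19393081244635879 2.1245261648760914
1.2918406804774865 0.13354504518990026
1.475444060851921 4.7756028604242076
1.8993108495004749 5.7560174614620854
1.9878546764263449 4.3515521358205236
1.0638719418553553 4.4299126955777828
1.7130581838620837 2.3976527517135868
1.6489295271944515 4.2631335233967524
1.1041516023056959 1.6725119376509254
1.2056654865525271 5.0423355117666224
2.7522956591721459 5.6134374007732601
1.9848868447411991 4.8024896606698286
1.1160214626517742 4.9294258900538592
1.3638801118854582 1.9273055866044164
1.464898162259034 1.956782769368083
1.7791870588019061 4.1488888918584825
1.4177626592435992 4.5819020059049711
1.0478142802886157 4.7950530599022878
0.66579707867364546 4.5241685294867588
0.51311366959474058 1.5012217242186527
1.4927719911974933 3.4643047791131396
2.1984501244827155 5.8811763311946361
0.56510655476527205 3.2354268713782557
1.7265782405519086 5.9005673563846859
0.29763507288163416 3.6568927968007547
1.4858745571970717 4.927003907117272
0.88611622325631678 1.9405832757722625
1.0154656430170219 0.99355705948305917
0.89199495000606421 1.2808753325373077
1.1829686258975036 5.306302140932571
1.4289742580360809 3.6857820101174208
2.2575575358173463 5.367399483855924
1.7335757621000401 1.7965743018838041
2.202725947619752 3.2368382191770793
2.4982572648670716 4.1253652027943781
0.88431154249110233 3.3843082343346285
2.8105294926697475 3.8736330714944387
1.9555903381289776 1.3165087123117551
2.1690543385563736 5.0105393181250326
0.81456954854374064 1.5408044143637403
0.30660489555087134 4.6388137135675134
1.1973864815025119 4.669023512186496
2.0147406709756166 5.9132647514704209
0.59289498342963287 5.886202445993538
0.81710552202771169 4.8878311714935361
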