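# t=58 symmetry=ico m_hemisphere=2040
1.5252359566171252 4.8418173476887461
1.3852533549551274 3.4972987754276326
2.3545500870490033 0.75563760612192643
0.48494728110931684 0.014619455090949562
1.2865163761938532 2.8819369459860749
1.4775928286073972 5.546761770305995
1.4139542194706423 1.6032010896394973
2.1862375202382913 4.3216360593204772
0.91349767545262917 1.6934005152422971
0.41747913133962339 2.8486066352599204
1.7750388976514984 4.2783422955719894
2.970913393934056 5.3655561214875958
1.9673731793315368 1.2857496794226864
1.7967342528010883 5.4892780422477845
1.887259603251586 3.364095153094893
1.9390835154946322 3.7299147738497962
2.7428101389818607 1.5900115864992026
2.9755852128735989 1.6741939292275518
2.3134256671803786 5.0145956523922797
2.4831008309016322 3.3569160488499117
1.4599151556349401 3.4989610761356706
1.2170758104517507 4.0091883541221014
2.1819107407556904 6.2529547677501585
1.0016197140581473 0.25317542990616709
2.3019652984181591 2.1177167584598555
2.4260839923316992 5.5764824398675756
2.587788901980165 1.0884613616591634
1.9599063063217694 2.3772941068942224
1.1829660383784291 4.7542976584949379
1.5247154764171362 0.8427974224616066
1.8654199745855979 0.60654279231724906
1.1353176630170081 0.88976679961556893
2.1422283021963366 6.1343477358469976
1.4031454912092927 1.2229309162778121
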