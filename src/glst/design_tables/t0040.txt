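# t=40 symmetry=ico m_hemisphere=1260
1.2729646411857445 4.0852325107114815
1.3051510669862723 4.8455815802181572
2.666049212035984 1.5542109476733401
1.9481059445281765 3.0719116677484104
1.1584408251271283 2.4398787938515261
0.57703841588143268 4.1796236878283679
1.3831548593663996 0.64448342429109073
1.9088355065765819 4.1595685217766132
1.2234541800361378 3.6053935525418379
2.1682134380087734 4.8095489950475301
2.1753271262641443 6.0168393622290184
1.0856149270667392 2.046407559488677
1.7159083524222416 5.6245405754871749
2.0057558538199602 1.4190346797313946
2.5626937976684641 2.9658098570990874
0.90226287224985469 2.3337416139569664
1.1134275685598616 5.9505714705288408
2.6179013363642878 1.9002635047287253
0.49056119757239486 3.2842538976446263
1.7639069350123169 1.3494718318584837
2.1190460082899945 2.0173646869378268
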