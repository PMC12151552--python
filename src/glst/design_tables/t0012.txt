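# t=12 symmetry=ico m_hemisphere=360
2.2459765013641348 6.9035075664668337
1.3520534940087172 0.72275580276428331
0.54485302637420163 4.2631925853437966
1.3814955339164756 5.1817342882535931
2.1416484196202585 2.0071797319153157
1.0863280222196596 2.2314506832832723
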