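# t=26 symmetry=ico m_hemisphere=720
0.26055230253768968 1.9302144825755239
0.81008347213232368 4.3639433119284137
1.0185594324624139 3.9857511856654564
1.5788005929098066 5.723929118622781
0.63263150797823864 0.34597605252947955
0.99823774595970827 2.9170442044856468
0.2136722168949641 2.7473817827497511
0.66015423396386996 2.2059590005970202
0.6267517668605862 2.0765711614702207
2.042080539218829 1.8965952706717855
1.0548770419513418 4.1452792364825468
2.2315278067117106 6.2337735817425814
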