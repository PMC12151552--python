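# t=14 symmetry=ico m_hemisphere=360
1.487063354800366 5.0638406279180854
2.2632408394829762 1.5009740547518513
0.79243940645847044 1.6231774694321175
1.9696244584717357 4.7786207684266948
1.195388125736309 5.7712474933250633
1.4396843990144339 1.5499906860115678
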