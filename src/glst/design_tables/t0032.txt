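# t=32 symmetry=ico m_hemisphere=960
2.3990148977820178 3.1294521482822795
0.52012771310166894 5.6016792477673798
0.3892851475522861 6.1101309259049179
0.32681767050964805 2.4240021779589931
0.67195443601028815 4.5380861816034734
1.4294768048151636 0.64742729449545844
3.0700600199932304 1.3935049260975654
2.9598556873149104 0.072929173883613238
2.1595282031506047 6.1651950109500584
1.8189931864390212 5.8211408493953192
1.4054993452443272 3.8923051107678694
0.26571711871776799 5.9533130701177468
1.6435891790775303 0.55634282216768005
1.9528125706495223 6.044822908220767
1.2914768716943079 4.1621956484922178
1.4162634206831402 3.2891838607611339
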