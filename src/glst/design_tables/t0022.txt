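# t=22 symmetry=ico m_hemisphere=600
1.719939688539468 5.0381952205398717
2.5150706305997161 1.4109904720787487
1.9898421976634728 1.463288079212004
1.4784222609328481 3.6367636230368445
2.4085451903739301 4.428469798475505
2.5598964601475398 0.70320753753214815
1.2063451084343872 2.8366006644945232
1.8156150533147708 1.7888304104710833
2.0487695595086888 2.1479758597911287
1.7837567071609446 2.5242133156215525
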