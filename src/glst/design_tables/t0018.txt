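# t=18 symmetry=ico m_hemisphere=480
0.54362002006162069 0.85148539905466614
1.8724127126947014 1.3641997245678612
1.8954876151923932 4.8381853871848461
2.1052662186097759 0.38976796866403274
2.2633042758033177 3.137433652838622
1.2549021486508858 3.2044407620521742
1.7688099853671102 0.37325718817747539
3.1743433054484922 3.195501712262232
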