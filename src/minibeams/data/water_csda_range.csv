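# CSDA range of protons in liquid water (density 1.0 g/cm^3).
# Values from the NIST PSTAR stopping-power and range tables (rounded);
# range converted from g/cm^2 to mm.
energy_MeV,csda_range_mm
1.0,0.02458
2.5,0.1166
5.0,0.3623
10.0,1.230
15.0,2.539
20.0,4.260
25.0,6.370
30.0,8.853
35.0,11.70
40.0,14.89
45.0,18.41
50.0,22.27
55.0,26.44
60.0,30.93
65.0,35.72
70.0,40.80
75.0,46.18
80.0,51.84
85.0,57.77
90.0,63.98
95.0,70.45
100.0,77.18
110.0,91.42
120.0,106.5
130.0,122.7
140.0,139.6
150.0,157.7
160.0,176.5
170.0,196.1
180.0,216.4
190.0,237.3
200.0,258.9
210.0,281.1
220.0,303.8
230.0,327.2
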