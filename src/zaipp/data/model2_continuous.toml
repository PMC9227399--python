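# Model 2 (enzyme-binding), continuous 25 uM exposure: published point estimates.
[za]
kZY = 0.007
kXY = 0.004
kYZ = 0.001
rhoZY = 25.46
kXZ = 0.0

[ag]
model = 2
kXG = 0.081
kXGU = 0.051
lambdaUBG = 1.806
kBUZ = 0.099
kUBG = 0.168
G0 = 27.32

[design]
mode = "continuous"
Y0 = 25.0
t_end = 48.0
sample_times = [1.0, 3.0, 6.0, 12.0, 18.0, 24.0, 48.0]
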