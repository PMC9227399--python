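# Model 1, continuous 25 uM exposure (MCF7): published point estimates.
[za]
kZY = 0.007
kXY = 0.004
kYZ = 0.001
rhoZY = 25.46
kXZ = 0.0

[ag]
model = 1
kXG = 0.101
kXGZ = 13.25
lambdaGZ = 0.195
G0 = 12.71

[design]
mode = "continuous"
Y0 = 25.0
t_end = 48.0
sample_times = [1.0, 3.0, 6.0, 12.0, 18.0, 24.0, 48.0]
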