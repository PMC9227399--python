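# Model 1, 1 h pulse exposure then washout: published point estimates.
[za]
kZY = 0.607
kXY = 0.029
kYZ = 18.06
rhoZY = 14.91
kXZ = 0.0
Ystar_plus = 0.0

[ag]
model = 1
kXG = 0.0
kXGZ = 2.391
lambdaGZ = 0.377
G0 = 2.704

[design]
mode = "pulse"
Y0 = 25.0
t_star = 1.0
t_end = 48.0
sample_times = [0.0, 1.0, 3.0, 6.0, 12.0, 18.0, 24.0, 48.0]
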