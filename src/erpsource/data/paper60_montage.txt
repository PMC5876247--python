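# Spherical angles (degrees) of the 60-channel extended 10/20 montage.
# Convention: azimuth from +x (nasion direction) toward the left ear (+y),
# elevation above the horizontal (Fpz-Oz) plane; all sites on the unit sphere.
# REF row: nose-tip reference position.
# name azimuth_deg elevation_deg
FP1 16.84 -6.89
FPz 0.50 -4.05
FP2 -15.83 -6.91
AF3 20.36 8.83
AF4 -20.15 9.16
F7 50.27 -10.48
F5 45.30 6.93
F3 36.26 22.82
F1 21.16 34.64
Fz 0.55 38.89
F2 -20.95 34.05
F4 -35.55 21.88
F6 -45.11 6.43
F8 -49.64 -10.62
FT7 69.30 -10.91
FC5 65.64 12.31
FC3 57.17 34.37
FC1 39.35 53.30
FCz 0.85 61.96
FC2 -37.98 53.12
FC4 -56.52 34.20
FC6 -64.93 12.19
FT8 -68.27 -11.09
T7 89.48 -10.03
C5 87.87 16.07
C3 85.56 41.36
C1 79.64 65.77
Cz 4.75 85.38
C2 -78.94 65.70
C4 -84.91 41.09
C6 -87.21 15.89
T8 -88.80 -10.26
TP7 108.80 -8.02
CP5 110.26 16.36
CP3 115.08 40.03
CP1 129.85 60.92
CPz 178.78 71.95
CP2 -129.04 60.49
CP4 -114.48 39.72
CP6 -109.61 16.26
TP8 -108.79 -8.19
P7 127.64 -5.06
P5 131.06 14.04
P3 138.92 31.41
P1 155.05 44.76
Pz 179.37 50.08
P2 -154.13 45.08
P4 -138.51 31.65
P6 -131.49 14.07
P8 -128.01 -5.16
PO7 145.32 -1.71
PO5 149.07 9.37
PO3 155.93 18.86
POz 179.45 27.73
PO4 -156.96 18.56
PO6 -149.45 9.47
PO8 -145.95 -1.76
O1 162.34 1.78
Oz 179.46 5.20
O2 -163.19 1.77
REF 0.00 -30.00
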