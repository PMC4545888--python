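# Fitted parameters, monkey M11 (set-size-4 fit).
# Times/delays in ms, threshold theta in kHz, weights and inputs dimensionless.
P_delay: 24.08
T_delay: 55.72
tau_m: 438.2
tau_it: 68.66
tau_aip: 119.7
tau_lip: 34.80
eta_maipit: 5.371
eta_lip: 2.936
eta_lip_decay1: 0.8470
eta_lip_decay2: 0.1300
alpha_lip: 1.469
w_aipm: 4.827
w_itaip: 10.98
w_lipaip: 6.495
w_aiplip: 6.276
beta_aiplip: 8.422
beta_maip: 3.108
beta_mitlip: 11.02
s_lip: 0.6317
s_tar: 0.3997
s_back: 0.5038
s_ori: 1.227
c_maip: 0.7866
c_it: 1.465
c_lip: 1.950
k_m: 0.0000
g_m: 0.1079
k_aip: 12.51
g_aip: 0.0005
T_0: 169.8
theta: 0.0926
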