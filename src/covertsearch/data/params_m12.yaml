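# Fitted parameters, monkey M12 (set-size-4 fit).
# Times/delays in ms, threshold theta in kHz, weights and inputs dimensionless.
P_delay: 44.58
T_delay: 48.20
tau_m: 438.2
tau_it: 68.66
tau_aip: 119.7
tau_lip: 34.80
eta_maipit: 5.371
eta_lip: 0.1032
eta_lip_decay1: 0.8470
eta_lip_decay2: 0.1300
alpha_lip: 1.469
w_aipm: 4.827
w_itaip: 18.75
w_lipaip: 2.520
w_aiplip: 1.166
beta_aiplip: 4.266
beta_maip: 3.108
beta_mitlip: 11.02
s_lip: 0.4088
s_tar: 0.4165
s_back: 0.5038
s_ori: 1.227
c_maip: 0.7866
c_it: 0.6744
c_lip: 1.818
k_m: 0.0000
g_m: 0.1079
k_aip: 12.51
g_aip: 0.0005
T_0: 96.17
theta: 0.0961
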