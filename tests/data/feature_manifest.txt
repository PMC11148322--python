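sdevF0.st
iqrF0.st
meanF0.st
MeanDur_intrapause
SdevDur_intrapause
pct_intrapause
IMC_RTEMP_RMAS_theta_alpha
IMC_RTEMP_RMAS_beta
IMC_RTEMP_RMAS_gamma
IMC_RTEMP_RABD_theta_alpha
IMC_RTEMP_RABD_beta
IMC_RTEMP_RABD_gamma
IMC_RABD_RMAS_theta_alpha
IMC_RABD_RMAS_beta
IMC_RABD_RMAS_gamma
density_RTEMP
density_RMAS
density_RABD
density_audio
mod_depth_theta_RTEMP
PSI_delta_theta_RTEMP
PSI_theta_beta.gamma_RTEMP
mod_depth_theta_RMAS
PSI_delta_theta_RMAS
PSI_theta_beta.gamma_RMAS
mod_depth_theta_RABD
PSI_delta_theta_RABD
PSI_theta_beta.gamma_RABD
hbenvlp_mod_depth_theta_100_300
hbenvlp_PSI_delta_theta_100_300
hbenvlp_PSI_theta_beta.gamma_100_300
hbenvlp_mod_depth_theta_300_800
hbenvlp_PSI_delta_theta_300_800
hbenvlp_PSI_theta_beta.gamma_300_800
hbenvlp_mod_depth_theta_1000_3000
hbenvlp_PSI_delta_theta_1000_3000
hbenvlp_PSI_theta_beta.gamma_1000_3000
hbenvlp_mod_depth_theta_3000_8000
hbenvlp_PSI_delta_theta_3000_8000
hbenvlp_PSI_theta_beta.gamma_3000_8000
DET_RTEMP
DET_RMAS
DET_RABD
DET_mfcc1
DET_mfcc2
DET_mfcc3
DET_mfcc4
DET_mfcc5
DET_mfcc6
DET_mfcc7
DET_mfcc8
DET_mfcc9
DET_mfcc10
DET_mfcc11
DET_mfcc12
DET_mfcc13
ShanEn_RTEMP
ShanEn_RMAS
ShanEn_RABD
ShanEn_audio
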