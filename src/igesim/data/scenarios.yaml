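# Scenario registry for the indirect-genetic-effects simulation study.
# One record per scenario; numeric fields reproduce the study's design
# tables exactly.  All scenarios share sigma2_aD = 192,000 kg^2 ECM,
# 10,000 phenotyped cows, 100 sires, and herd effects uniform on
# [8000, 13000] kg ECM.  The genetic covariance is derived from r_g at
# load time (sigma_aDI = r_g * sqrt(sigma2_aD * sigma2_aI)).

scenarios:
  # --- basic scenario and variations of r_g and herd size -------------
  - {scenario_id: 1,  name: basic,            n_herds: 100, herd_size: 100,
     sigma2_aD: 192000, sigma2_aI: 6400, sigma2_eI: 6400, sigma2_e: 64000, r_g: 0.0}
  - {scenario_id: 2,  name: rg_neg,           n_herds: 100, herd_size: 100,
     sigma2_aD: 192000, sigma2_aI: 6400, sigma2_eI: 6400, sigma2_e: 64000, r_g: -0.6}
  - {scenario_id: 3,  name: rg_pos,           n_herds: 100, herd_size: 100,
     sigma2_aD: 192000, sigma2_aI: 6400, sigma2_eI: 6400, sigma2_e: 64000, r_g: 0.6}
  - {scenario_id: 4,  name: herd50,           n_herds: 200, herd_size: 50,
     sigma2_aD: 192000, sigma2_aI: 6400, sigma2_eI: 6400, sigma2_e: 64000, r_g: 0.0}
  - {scenario_id: 5,  name: herd200,          n_herds: 50,  herd_size: 200,
     sigma2_aD: 192000, sigma2_aI: 6400, sigma2_eI: 6400, sigma2_e: 64000, r_g: 0.0}

  # --- smaller indirect genetic variance (15% of sigma2_P) ------------
  - {scenario_id: 6,  name: ige15_herd100,    n_herds: 100, herd_size: 100,
     sigma2_aD: 192000, sigma2_aI: 3200, sigma2_eI: 3200, sigma2_e: 256000, r_g: 0.0}
  - {scenario_id: 7,  name: ige15_herd50,     n_herds: 200, herd_size: 50,
     sigma2_aD: 192000, sigma2_aI: 3200, sigma2_eI: 3200, sigma2_e: 256000, r_g: 0.0}
  - {scenario_id: 8,  name: ige15_herd200,    n_herds: 50,  herd_size: 200,
     sigma2_aD: 192000, sigma2_aI: 3200, sigma2_eI: 3200, sigma2_e: 256000, r_g: 0.0}

  # --- 5% of sigma2_P -------------------------------------------------
  - {scenario_id: 9,  name: ige5_herd100,     n_herds: 100, herd_size: 100,
     sigma2_aD: 192000, sigma2_aI: 1024, sigma2_eI: 1024, sigma2_e: 386560, r_g: 0.0}
  - {scenario_id: 10, name: ige5_herd50,      n_herds: 200, herd_size: 50,
     sigma2_aD: 192000, sigma2_aI: 1024, sigma2_eI: 1024, sigma2_e: 386560, r_g: 0.0}
  - {scenario_id: 11, name: ige5_herd200,     n_herds: 50,  herd_size: 200,
     sigma2_aD: 192000, sigma2_aI: 1024, sigma2_eI: 1024, sigma2_e: 386560, r_g: 0.0}

  # --- 3% of sigma2_P -------------------------------------------------
  - {scenario_id: 12, name: ige3_herd100,     n_herds: 100, herd_size: 100,
     sigma2_aD: 192000, sigma2_aI: 640, sigma2_eI: 640, sigma2_e: 409600, r_g: 0.0}
  - {scenario_id: 13, name: ige3_herd50,      n_herds: 200, herd_size: 50,
     sigma2_aD: 192000, sigma2_aI: 640, sigma2_eI: 640, sigma2_e: 409600, r_g: 0.0}
  - {scenario_id: 14, name: ige3_herd200,     n_herds: 50,  herd_size: 200,
     sigma2_aD: 192000, sigma2_aI: 640, sigma2_eI: 640, sigma2_e: 409600, r_g: 0.0}

  # --- 1.5% of sigma2_P -----------------------------------------------
  - {scenario_id: 15, name: ige1p5_herd100,   n_herds: 100, herd_size: 100,
     sigma2_aD: 192000, sigma2_aI: 320, sigma2_eI: 320, sigma2_e: 428800, r_g: 0.0}
  - {scenario_id: 16, name: ige1p5_herd50,    n_herds: 200, herd_size: 50,
     sigma2_aD: 192000, sigma2_aI: 320, sigma2_eI: 320, sigma2_e: 428800, r_g: 0.0}
  - {scenario_id: 17, name: ige1p5_herd200,   n_herds: 50,  herd_size: 200,
     sigma2_aD: 192000, sigma2_aI: 320, sigma2_eI: 320, sigma2_e: 428800, r_g: 0.0}

  # --- intensity of contact (simulate once, analyse differently) ------
  - {scenario_id: 18, name: with_intensities, n_herds: 100, herd_size: 100,
     sigma2_aD: 192000, sigma2_aI: 6400, sigma2_eI: 6400, sigma2_e: 64000, r_g: 0.0,
     intensity_mode: standardized, analysis_intensity: use_true}
  - {scenario_id: 19, name: without_intensities, n_herds: 100, herd_size: 100,
     sigma2_aD: 192000, sigma2_aI: 6400, sigma2_eI: 6400, sigma2_e: 64000, r_g: 0.0,
     intensity_mode: standardized, analysis_intensity: ignore}
  - {scenario_id: 20, name: imprecise_intensities, n_herds: 100, herd_size: 100,
     sigma2_aD: 192000, sigma2_aI: 6400, sigma2_eI: 6400, sigma2_e: 64000, r_g: 0.0,
     intensity_mode: standardized, intensity_noise_var: 0.16,
     analysis_intensity: use_noisy}

  # --- direction of contact -------------------------------------------
  - {scenario_id: 21, name: with_direction,   n_herds: 100, herd_size: 100,
     sigma2_aD: 192000, sigma2_aI: 6400, sigma2_eI: 6400, sigma2_e: 64000, r_g: 0.0,
     direction_mode: directed, analysis_direction: as_simulated}
  - {scenario_id: 22, name: without_direction, n_herds: 100, herd_size: 100,
     sigma2_aD: 192000, sigma2_aI: 6400, sigma2_eI: 6400, sigma2_e: 64000, r_g: 0.0,
     direction_mode: directed, analysis_direction: ignore_direction}
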