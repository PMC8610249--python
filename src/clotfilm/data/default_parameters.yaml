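# Kinetic parameterization of the reduced thin-film clotting model.
#
# Each catalytic reaction is linearized Michaelis-Menten: with the zymogen
# substrate clamped at its plasma level S0 (replenished by diffusion from
# flowing blood), the reaction is first order in its enzyme with rate
# alpha = kcat*S0/(Km + S0), attenuated by the effectiveness factor eta
# (actual rate / transport-unlimited rate).  alpha_printed is the published
# first-order rate for regression comparison; it is NOT used by default
# (alphas are recomputed from kcat, Km and S0, which is required anyway to
# rescale them when plasma levels are varied).
#
# Units: S0 and Km in uM, kcat in 1/s, kf in 1/(uM*s), kr in 1/s.
reactions:
  - id: 1
    enzyme: "TF:VIIa"
    product: "Xa"
    substrate: "FX"
    S0: 0.17
    kcat: 1.15
    Km: 0.24
    eta: 1.0
    alpha_printed: 0.46
  - id: 2
    enzyme: "TF:VIIa"
    product: "IXa"
    substrate: "FIX"
    S0: 0.09
    kcat: 1.8
    Km: 0.42
    eta: 1.0
    alpha_printed: 0.32
  - id: 3
    enzyme: "IXa:VIIIa"
    product: "Xa"
    substrate: "FX"
    S0: 0.17
    kcat: 8.2
    Km: 0.082
    eta: 1.0
    alpha_printed: 5.42
  - id: 4
    enzyme: "Xa:Va"
    product: "IIa"
    substrate: "FII"
    S0: 1.4
    kcat: 30.0
    Km: 0.3
    eta: 0.18
    alpha_printed: 24.7
  - id: 5
    enzyme: "IIa"
    product: "fibrin"
    substrate: "fibrinogen"
    S0: 18.0
    kcat: 80.0
    Km: 6.5
    eta: 0.05
    alpha_printed: 5.88
  - id: 6
    enzyme: "IIa"
    product: "XIa"
    substrate: "FXI"
    S0: 0.031
    kcat: 1.3e-4
    Km: 0.05
    eta: 0.36
    alpha_printed: 4.98e-5
  - id: 7
    enzyme: "XIa"
    product: "IXa"
    substrate: "FIX"
    S0: 0.09
    kcat: 0.21
    Km: 0.2
    eta: 1.0
    alpha_printed: 0.065

# Reversible, kinetically controlled adsorption of thrombin to fibrin
# ("antithrombin-I" activity): a weak exosite-I site in the fibrin E domain
# (Kd = kr/kf = 2.8 uM) and a high-affinity exosite-II site on the
# gamma'-chain splice variant (Kd = 0.1 uM).  sites_per_fibrin is the
# effective number of binding sites generated per uM of fibrin monomer
# formed; absolute baseline site densities are not published, so these two
# stoichiometries are calibration parameters (see docs/methods.md).  The
# shipped values were calibrated against the ensemble-mean free-thrombin
# level (~50 nM) and the one-at-a-time FIX sensitivity (+100% total
# thrombin at FIX 150%).
binding_sites:
  - site_id: "weak_E"
    kf: 100.0
    kr: 280.0
    sites_per_fibrin: 1.0
  - site_id: "gamma_prime"
    kf: 100.0
    kr: 10.0
    sites_per_fibrin: 0.25
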