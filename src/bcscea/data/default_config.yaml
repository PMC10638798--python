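# Packaged base-case parameters (2020 SEK, one-year cycles).
# Keys follow the evidence table's short names; any key may be omitted and
# falls back to the packaged default.  Gamma PSA entries are
# (shape, scale) -- shape x scale equals the deterministic mean; Beta entries
# are (alpha, beta).  Shared short names: 'cbl' (State B cost, both
# lumpectomy arms), 'ual' (State A utility, both lumpectomy arms),
# 'infocare' (full amount; the no-irradiation arm gets half).
age: 58
horizon: 30
cycle_length: 1.0
irr: 1.27
tpA2B:
  mastectomy:
  - - 0
    - 5
    - 56.46
  - - 5
    - 10
    - 26.77
  - - 10
    - 30
    - 7.09
  lumpectomy_no_rt:
  - - 0
    - 5
    - 71.7
  - - 5
    - 10
    - 34.0
  - - 10
    - 30
    - 9.0
  lumpectomy_rt:
  - - 0
    - 5
    - 36.9
  - - 5
    - 10
    - 24.3
  - - 10
    - 30
    - 8.3
cDR: 0.03
oDR: 0.03
psa:
  age:
  - normal
  - 58.0
  - 11.8
  tpA2B:
  - beta
  - 54.84
  - 944.16
  tpA2D:
  - beta
  - 7.7
  - 991.3
  tpB2C:
  - beta
  - 164.52
  - 834.48
  tpB2F:
  - beta
  - 65.05
  - 933.95
  tpC2D:
  - beta
  - 230.16
  - 768.84
  tpD2E:
  - beta
  - 374.33
  - 624.67
  tpD2F:
  - beta
  - 178.31
  - 820.69
  cam:
  - gamma
  - 656.5
  - 133.54
  cal_wo:
  - gamma
  - 4253.8
  - 6.5
  cal_w:
  - gamma
  - 6217.04
  - 8.1
  cbm:
  - gamma
  - 26.7
  - 662.2
  cbl:
  - gamma
  - 42749.59
  - 2.05
  cd:
  - gamma
  - 1386844.91
  - 0.36
  uam:
  - beta
  - 839.16
  - 159.84
  ual:
  - beta
  - 869.13
  - 129.87
  ub:
  - beta
  - 778.22
  - 220.78
  uc:
  - beta
  - 808.69
  - 190.31
  ud:
  - beta
  - 684.32
  - 314.69
  ue:
  - beta
  - 761.74
  - 237.26
tpA2D: 0.008
tpB2C: 0.165
tpB2F: 0.065
tpC2D: 0.23
tpD2E: 0.375
tpD2F: 0.178
cam: 87670.0
cal_wo: 27655.0
cal_w: 50352.0
cbm: 17680.0
cbl_wo: 87670.0
cbl_w: 87670.0
cd: 499343.0
infocare_m: 10003.0
infocare_l_wo: 5002.0
infocare_l_w: 10003.0
prod: 4104.0
drg_lump_no_rt: 36439.0
uam: 0.84
ual_wo: 0.87
ual_w: 0.87
ub: 0.78
uc: 0.81
ud: 0.69
ue: 0.76
perspective: healthcare
charge_entry_cost: true
state_a_running_cost: true
informal_care_scope: flat_annuity
productivity_alive_weighted: false
background_mortality_additive: true
half_cycle_correction: false
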