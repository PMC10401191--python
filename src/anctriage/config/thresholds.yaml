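# Versioned decision-table band edges for the three priority conditions.
# Every band is lower-inclusive: a value exactly at an edge takes the MORE
# severe colour. The engine refuses to start if any key is missing.
version: 1

bp:
  sbp_yellow: 140    # mmHg; 140 <= sbp < sbp_red -> YELLOW
  sbp_red: 160       # mmHg; sbp >= 160 -> RED (severe hypertension)
  dbp_yellow: 90     # mmHg
  dbp_red: 110       # mmHg
  si_yellow: 0.9     # shock index = heart_rate / sbp
  si_red: 1.7

hb:
  red_below: 7.0       # g/dL; hb < 7.0 -> RED (severe anaemia, urgent referral)
  referral_below: 10.0 # g/dL; hb < 10.0 within YELLOW -> referral-strength advice
  yellow_below: 11.0   # g/dL; 7.0 <= hb < 11.0 -> YELLOW; hb >= 11.0 -> GREEN

ogtt:
  yellow_at: 140   # mg/dL; 2-h glucose >= 140 -> YELLOW (GDM, refer to PHC)
  red_at: 200      # mg/dL; >= 200 -> RED (overt diabetes, urgent referral)

units:
  sbp: mmHg
  dbp: mmHg
  heart_rate: bpm
  shock_index: ratio
  hb: g/dL
  ogtt_2h_glucose: mg/dL

# Resolution steps per measurement, used for boundary enrichment and
# mutation-sensitivity checks.
resolution:
  bp: 1
  heart_rate: 1
  si: 0.01
  hb: 0.1
  glucose: 1
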