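# Full pipeline config: simulate a synthetic report database, then run
# read -> dedup -> count -> mgps -> screen on it.
#   pvsignal simulate --config examples/config.yaml
#   pvsignal run      --config examples/config.yaml
io:
  demo: pvsignal_out/demo.txt
  drug: pvsignal_out/drug.txt
  reac: pvsignal_out/reac.txt
  dialect:
    delimiter: "$"
    has_header: true
output_dir: pvsignal_out

# restrict counting to the simulated drug vocabulary
drugs: [drug01, drug02, drug03, drug04, drug05, drug06, drug07, drug08,
        drug09, drug10, drug11, drug12, drug13, drug14, drug15, drug16,
        drug17, drug18, drug19, drug20]

# one single-PT term per simulated event
terms:
  event01: [event01]
  event02: [event02]
  event03: [event03]
  event04: [event04]
  event05: [event05]
  event06: [event06]
  event07: [event07]
  event08: [event08]
  event09: [event09]
  event10: [event10]
  event11: [event11]
  event12: [event12]
  event13: [event13]
  event14: [event14]
  event15: [event15]

dedup:
  enabled: true
  keep_rule: latest_receipt
  age_tolerance_years: 1.0

mgps:
  seed: 11
  n_restarts: 5

threshold: 2.0

simulate:
  n_reports: 20000
  seed: 7
  background: "null"        # lambda = 1 everywhere except planted pairs
  planted_signals:
    - {drug: drug10, pt: event08, true_lambda: 10.0}
  duplicate_fraction: 0.05
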