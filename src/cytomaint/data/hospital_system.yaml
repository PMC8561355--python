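schema: cytomaint/system-v1
name: cytostatic preparation hood
n_units: 1
sections:
  - name: filter
    failure_rate: 0.000114
    repair_rate: 0.0417
  - name: gas_extraction
    failure_rate: 0.000057
    repair_rate: 0.021
  - name: control_alarms
    failure_rate: 0.000038
    repair_rate: 0.021
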