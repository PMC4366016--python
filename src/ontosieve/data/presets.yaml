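# Per-ontology tuning presets (independence-interval constants m/n and the
# global outlier constant k) for the six CRAFT ontologies.
craft-CL:      {m: 0.8, n: 0.0, k: 3}
craft-GO_CC:   {m: 0.9, n: 0.0, k: 3}
craft-GO_BPMF: {m: 1.0, n: 0.1, k: 3}
craft-ChEBI:   {m: 0.9, n: 0.0, k: 3}
craft-PRO:     {m: 1.0, n: 0.2, k: 3}
craft-SO:      {m: 0.7, n: 0.0, k: 3}
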