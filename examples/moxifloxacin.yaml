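# Moxifloxacin channel-block inputs at the free Cmax after a 400 mg oral
# dose.  Usable with `cardiocirc trial --drug examples/moxifloxacin.yaml`.
- {channel: IKr, ic50_um: 29.0, hill_n: 1.0, conc_um: 3.8}
- {channel: INa, ic50_um: 127.2, hill_n: 1.0, conc_um: 3.8}
- {channel: ICa, ic50_um: 168.9, hill_n: 1.0, conc_um: 3.8}
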