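# Chevron arm-angle sweep at fixed incision length, each angle calibrated to
# the IOL-injector opening.
protocol: sweep-chevron
plate:
  width: "60 mm"
  height: "60 mm"
shape:
  family: chevron
  total_length: "2.2 mm"
  alpha: "150 deg"
material:
  kind: isotropic
  E: "9.82 MPa"
  nu: 0.49
  G_c: "5.40 kJ/m^2"
d_target: "1.73 mm"
refine: true
output_dir: out/chevron_sweep
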