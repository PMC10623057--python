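# Single chevron case at the printed load: solve, export fields, report the
# per-ring contour ERR at both tips.
protocol: solve
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
sigma0: "3.95 MPa"
output_dir: out/chevron150
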