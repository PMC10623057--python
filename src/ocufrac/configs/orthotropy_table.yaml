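# Chevron ERR against the material orthotropy ratio for several arm angles.
protocol: orthotropy-table
plate:
  width: "60 mm"
  height: "60 mm"
etas: [2, 1.5, 1, 0.75, 0.5]
angles: ["165 deg", "170 deg", "175 deg", "180 deg"]
d_target: "1.73 mm"
output_dir: out/orthotropy
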