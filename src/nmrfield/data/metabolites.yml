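# Default metabolite library for the synthetic tissue-extract cohort.
#
# Peak positions are literature 1H chemical shifts of the usual quantification
# resonances (library defaults, editable); multiplets are encoded as explicit
# peak lists [center_ppm, relative_intensity, linewidth_hz] with no J-coupling
# fine structure.  base_log_concentration sets the noise-free peak amplitude
# scale (natural-log units).  jitter: false marks the chemical-shift reference
# (TSP), which does not move with sample pH.
spectrometer_mhz: 600.0
metabolites:
  - {name: TSP, base_log_concentration: 1.1, jitter: false,
     peaks: [[0.000, 1.00, 1.2]]}
  - {name: lactate, base_log_concentration: 0.8,
     peaks: [[1.330, 1.00, 1.5], [4.110, 0.25, 1.8]]}
  - {name: alanine, base_log_concentration: 0.2,
     peaks: [[1.480, 1.00, 1.5]]}
  - {name: 3-hydroxybutyrate, base_log_concentration: 0.1,
     peaks: [[1.200, 1.00, 1.5], [2.310, 0.35, 2.0]]}
  - {name: valine, base_log_concentration: 0.0,
     peaks: [[0.990, 1.00, 1.5], [1.040, 0.95, 1.5]]}
  - {name: leucine, base_log_concentration: 0.0,
     peaks: [[0.960, 1.00, 1.5]]}
  - {name: isoleucine, base_log_concentration: -0.2,
     peaks: [[0.940, 0.80, 1.5], [1.010, 0.60, 1.5]]}
  - {name: propionate, base_log_concentration: -0.3,
     peaks: [[1.060, 1.00, 1.5], [2.180, 0.60, 1.8]]}
  - {name: acetate, base_log_concentration: 0.3,
     peaks: [[1.920, 1.00, 1.3]]}
  - {name: glutamate, base_log_concentration: 0.4,
     peaks: [[2.080, 0.70, 2.2], [2.350, 1.00, 2.2]]}
  - {name: glutamine, base_log_concentration: 0.4,
     peaks: [[2.140, 0.70, 2.2], [2.450, 1.00, 2.2]]}
  - {name: succinate, base_log_concentration: 0.1,
     peaks: [[2.410, 1.00, 1.3]]}
  - {name: aspartate, base_log_concentration: 0.0,
     peaks: [[2.680, 0.80, 2.2], [2.800, 1.00, 2.2]]}
  - {name: creatine, base_log_concentration: 0.5,
     peaks: [[3.040, 1.00, 1.3], [3.930, 0.70, 1.5]]}
  - {name: choline, base_log_concentration: 0.2,
     peaks: [[3.200, 1.00, 1.3]]}
  - {name: phosphocholine, base_log_concentration: 0.3,
     peaks: [[3.220, 1.00, 1.3]]}
  - {name: glycerophosphocholine, base_log_concentration: 0.3,
     peaks: [[3.230, 1.00, 1.3], [4.320, 0.25, 2.0]]}
  - {name: taurine, base_log_concentration: 0.2,
     peaks: [[3.260, 0.80, 1.8], [3.420, 1.00, 1.8]]}
  - {name: glycine, base_log_concentration: 0.3,
     peaks: [[3.560, 1.00, 1.3]]}
  - {name: myoinositol, base_log_concentration: 0.5,
     peaks: [[3.280, 0.50, 1.8], [3.540, 0.80, 1.8], [3.620, 1.00, 1.8],
             [4.060, 0.60, 1.8]]}
  - {name: glucose, base_log_concentration: 0.5,
     peaks: [[4.640, 0.60, 1.8], [5.230, 1.00, 1.8]]}
  - {name: fumarate, base_log_concentration: -0.5,
     peaks: [[6.520, 1.00, 1.3]]}
  - {name: inosine, base_log_concentration: -0.3,
     peaks: [[6.100, 0.50, 1.8], [8.240, 0.80, 1.5], [8.340, 1.00, 1.5]]}
  - {name: hypoxanthine, base_log_concentration: -0.3,
     peaks: [[8.190, 1.00, 1.4], [8.210, 0.95, 1.4]]}
  - {name: ADP, base_log_concentration: -0.2,
     peaks: [[6.140, 0.40, 2.0], [8.270, 0.80, 2.0], [8.530, 1.00, 2.0]]}
  - {name: formate, base_log_concentration: -0.4,
     peaks: [[8.460, 1.00, 1.3]]}
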