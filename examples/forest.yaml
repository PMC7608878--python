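# Two-species forest on a 20 m x 20 m field with a 12-pose figure-eight
# fly-through. Intensities are mixtures of squared-exponential kernels;
# h and l are the kernel scale lengths in metres (denominators h^2, l^2).
seed: 11
min_spacing: 1.0
species:
  - label: maple
    intensity:
      domain: [0, 20, 0, 20]
      components:
        - {C: 0.4, cx: 5, cy: 5, h: 2.236, l: 2.449}
    tree:
      iterations: 1
      template: {sub_branches: 3, curvature: 0.15, leaf_count: 40, leaf_size: 0.05}
      leaf_radius_mean: 0.05
      leaf_radius_sd: 0.01
  - label: hazelnut
    intensity:
      domain: [0, 20, 0, 20]
      components:
        - {C: 0.3, cx: 15, cy: 15, h: 1.732, l: 2.449}
    tree:
      iterations: 1
      template: {sub_branches: 2, curvature: 0.2, leaf_count: 30, leaf_size: 0.04}
path: {lobe: 10, height: 3, n_points: 12}
beamwidth: {interval: [30, 65]}
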