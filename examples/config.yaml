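# Example run configuration for `crossepi run-all --config examples/config.yaml`.
#
# Marker ids follow the generated panel naming <cross>_c<chrom>_<index>;
# run `crossepi simulate` once to inspect the panel of a given spacing.

seed: 1
outdir: out/example

crosses:
  - name: AxB
    strains: [B, A]
    generations:
      - {label: F2, n: 3000}
    map_spacing_mb: 21.0     # sparse F2-style panel, 1 cM = 2 Mb
  - name: FxB
    strains: [B, F]
    generations:
      - {label: F2, n: 3000}
      - {label: F10, n: 1200}
      - {label: F14, n: 1200}
    map_spacing_mb: 7.0      # denser combined panel

# per-cross penetrance architecture: baseline + single-locus offsets
# (indexed BB, het, XX) + 3x3 two-locus deviation matrices
penetrance:
  AxB:
    ASD:
      baseline: 0.13
      locus_effects:
        AxB_c3_3: [-0.02, 0.0, 0.02]
        AxB_c4_3: [-0.015, 0.0, 0.015]
      pair_deviations:
        "AxB_c3_3,AxB_c4_3":
          [[-0.012, 0.0, 0.012], [0.0, 0.0, 0.0], [0.012, 0.0, -0.012]]
    AVSD:
      baseline: 0.045
      locus_effects:
        AxB_c5_3: [-0.01, 0.0, 0.01]
      pair_deviations:
        "AxB_c5_3,AxB_c16_2":
          [[-0.028, 0.0, 0.028], [0.0, 0.0, 0.0], [0.028, 0.0, -0.028]]
  FxB:
    ASD:
      baseline: 0.13
      locus_effects:
        FxB_c3_11: [-0.02, 0.0, 0.02]

severity: {ASD: 1, mVSD: 2, muVSD: 2, AVSD: 3}

qc_max_missing: 0.10   # strict >10% missingness filter
mask_rate: 0.03        # fraction of genotype calls hidden before imputation
error_rate: 0.005      # HMM genotyping error rate
n_perm: 1000           # permutations for F2 LOD thresholds
alphas: [0.05, 0.2]
max_pairs_per_defect: 6
locus_window_bp: 10000000
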