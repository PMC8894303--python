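# Published per-group summary statistics (mean, SD) of the twelve GLCM
# texture features at the subject level, for the two pulmonary-edema
# classes discriminated by the method: ARDS (permeability edema, n = 8)
# and CPE (cardiogenic/hydrostatic edema, n = 16).  Features are in
# quantized-level units (Ng = 16); entropies in bits.
# cluster_prominence was computed but not reported per group, hence absent.
groups:
  ARDS:
    n: 8
    features:
      contrast: {mean: 6.27, sd: 2.76}
      cluster_shade: {mean: 104.13, sd: 114.69}
      entropy: {mean: 4.00, sd: 0.21}
      variance: {mean: 23.11, sd: 6.24}
      mean: {mean: 5.79, sd: 1.26}
      correlation: {mean: 0.88, sd: 0.03}
      energy: {mean: 0.03, sd: 0.01}
      homogeneity: {mean: 0.65, sd: 0.04}
      mean_sum: {mean: 11.58, sd: 2.53}
      entropy_sum: {mean: 3.09, sd: 0.13}
      variance_sum: {mean: 125.30, sd: 45.16}
  CPE:
    n: 16
    features:
      contrast: {mean: 10.72, sd: 2.26}
      cluster_shade: {mean: -56.22, sd: 45.58}
      entropy: {mean: 4.26, sd: 0.11}
      variance: {mean: 18.32, sd: 2.46}
      mean: {mean: 8.87, sd: 0.89}
      correlation: {mean: 0.74, sd: 0.06}
      energy: {mean: 0.02, sd: 0.01}
      homogeneity: {mean: 0.56, sd: 0.03}
      mean_sum: {mean: 17.73, sd: 1.77}
      entropy_sum: {mean: 3.06, sd: 0.07}
      variance_sum: {mean: 252.05, sd: 52.62}
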