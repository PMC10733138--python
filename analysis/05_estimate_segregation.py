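#!/usr/bin/env python
"""Estimate exposure segregation and show why the correction matters.

Reports the study city's naive and attenuation-corrected exposure
segregation, the neighbourhood sorting index, and the decomposition by
home-tract component, tie strength, and 3-hour time window (all computed
by the pipeline).  Then reruns the debiasing simulation at several true
correlations to show the naive estimator's attenuation and the mixed
model's removal of it.
"""

import pandas as pd

from exposeg.experiments import debiasing_study
from common import RESULTS, run_study_pipeline


def main():
    res = run_study_pipeline()
    seg = res["segregation"]
    seg.to_csv(RESULTS / "05_segregation.csv", index=False)

    top = seg[seg["stratum"] == "all"].set_index("method")["estimate"]
    print(f"Study city: naive {top['naive']:.3f}, corrected {top['mixed']:.3f}, "
          f"neighbourhood sorting index {top['nsi']:.3f}.")
    comp = seg[seg["stratum"].str.startswith("component=")]
    for _, r in comp.iterrows():
        print(f"  {r.stratum.split('=')[1]:26s} -> {r.estimate:+.3f} "
              f"({r.n_egos:.0f} egos)")

    rows = []
    for rho in (0.0, 0.25, 0.5, 0.75):
        d = debiasing_study(rho=rho, n_egos=2000, partners_per_ego=3,
                            n_replicates=50, seed=1)
        rows.append({"true_correlation": rho,
                     "naive_mean_bias": round(d.naive_mean_bias, 4),
                     "mixed_mean_bias": round(d.mixed_mean_bias, 4)})
    bias = pd.DataFrame(rows)
    bias.to_csv(RESULTS / "05_debiasing.csv", index=False)
    print("\nAttenuation of the naive estimator (3 partners/ego, 2,000 egos,"
          " 50 replicates):")
    print(bias.to_string(index=False))
    print("The naive sample correlation is biased toward 0 whenever partner"
          " sets are small; the mixed-model correction is centred on the"
          " truth (the 0-truth row is noisier: the corrected ratio is"
          " boundary-unstable at the null, see docs/methods.md).")


if __name__ == "__main__":
    main()
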