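"""Outlier-robust super-resolution reconstruction with motion correction.

Runs the full two-step iterative pipeline (slice-to-volume registration +
robust SRR, beta schedule 0.5 / 0.65 / 0.8) on a corrupted simulated
acquisition and scores the result against the known phantom. Takes a few
minutes on one CPU.
"""

import numpy as np

from fetalrecon import outlier_robustness_experiment

out = outlier_robustness_experiment(seed=1)

print(f"final inliers: {out['n_final_inliers']} slices; "
      f"{out['n_true_outliers']} slices were corrupted in simulation")
print(f"outlier-rejection recall: {out['outlier_recall']:.2f} "
      f"({out['n_qualifying_outliers']} corrupted slices below the final "
      "threshold, all rejected)" if not out["missed"] else out["missed"])
print(f"masked PSNR vs phantom: reconstruction {out['masked_psnr_db']:.1f} dB"
      f" | best single input stack {out['masked_psnr_best_stack_db']:.1f} dB"
      f" | rejection disabled {out['masked_psnr_no_rejection_db']:.1f} dB")
print("-> the robust reconstruction beats any single stack, and switching "
      "off outlier rejection costs several dB: corrupted slices would "
      "otherwise contaminate the least-squares solve.")
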