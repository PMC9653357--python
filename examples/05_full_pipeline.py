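"""Run the end-to-end pipeline from a config dict and read the report.

The same entry point drives the CLI (`strokepred evaluate`); the report is
a pure function of (config, seed) and reruns are byte-identical.
"""

import strokepred as sp

config = {
    "seed": 11,
    "families": ["ridge", "lasso"],
    "n_repeats": 15,
    "importance_top_k": 3,
    "overlap_top_k": 10,
    "synthetic": {
        "n_patients": 62, "n_regions": 120, "n_components": 12,
        "n_active": 4, "k_active": 4,
    },
}
report = sp.run_pipeline(config)

print(f"patients {report['n_patients']}, components {report['n_components']}, "
      f"mean adjusted R2 {report['adj_r2_mean']:.3f}")
print(f"{'family':<8}{'side':<8}{'tp':<5}{'mode R2':>8}")
for row in report["mode_r2"]:
    print(f"{row['family']:<8}{row['side']:<8}{row['timepoint']:<5}"
          f"{row['r2_mode']:>8.3f}")
cell = report["overlap"]["right_2w"]
print(f"ridge top-10 vs lasso retained (right, 2w): {cell['overlap']} shared")
top = report["importance"]["right_2w"]
print("top-3 ridge components (right, 2w):",
      ", ".join(f"{c} ({v:.3f})" for c, v in top))
# Mode R² per cell is the analysis's headline table; the importance ranking
# names the disconnection components that carry the prediction.
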