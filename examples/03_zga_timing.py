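"""Minute-scale timing of zygotic genome activation (ZGA).

Pools cells into 5-min pseudobulk bins across 0-3 h, estimates each
zygotic gene's onset (half-max crossing), and checks how well the planted
activation order is recovered.  Also demonstrates pioneer behaviour:
regions linked to half the genes are planted to open 0.5 h before the
gene turns on, and the accessibility onset leads accordingly.
"""

import numpy as np
from scipy.stats import spearmanr

import embryochron as ec

onsets = np.linspace(0.5, 2.0, 50)
kin = [ec.KineticParams(f"g{i:04d}", "zygotic", onset_h=float(t), rate=6.0,
                        amplitude=2.0, access_lead_h=0.5 if i % 2 == 0 else 0.0)
       for i, t in enumerate(onsets)]
kin += [ec.KineticParams(f"bg{i:03d}", "constant", amplitude=4.0)
        for i in range(100)]  # maternal-like pool keeping library totals stable

cfg = ec.AtlasConfig(windows=[ec.CollectionWindow(0, 0.0, 3.0)],
                     cells_per_window_rna=8000, cells_per_window_atac=8000,
                     kinetics=kin, n_background_peaks=300,
                     lineage_tree=ec.binary_lineage_tree((1,), (0.0, 20.0)),
                     contamination_rate=0.0, contaminated_windows=())
atlas = ec.simulate_atlas(cfg, seed=2)

ages = atlas.rna.obs["true_age_h"].to_numpy()
bins = ec.fine_bins(ages, 5.0, (0.0, 3.0))
prof = ec.smooth_profile(
    ec.pseudobulk_profile(atlas.rna.X, list(atlas.rna.var_names), bins,
                          5.0, (0.0, 3.0)), 5)
est = [ec.onset_time(prof.values[i], prof.bin_edges) for i in range(50)]
rho = spearmanr(onsets, est).statistic
print(f"Spearman(planted onset, estimated onset) over 50 ZGA genes: {rho:.3f}")

ages_a = atlas.atac.obs["true_age_h"].to_numpy()
act = ec.smooth_profile(
    ec.aggregate_region_accessibility(
        atlas.atac.X, list(atlas.atac.var_names), atlas.gene_regions,
        ec.fine_bins(ages_a, 1.0, (0.0, 3.0)), 1.0, (0.0, 3.0)), 9)
expr1 = ec.smooth_profile(
    ec.pseudobulk_profile(atlas.rna.X, list(atlas.rna.var_names),
                          ec.fine_bins(ages, 1.0, (0.0, 3.0)), 1.0,
                          (0.0, 3.0)), 9)
gpos = {g: i for i, g in enumerate(expr1.feature_ids)}
apos = {g: i for i, g in enumerate(act.feature_ids)}
leads = [ec.onset_time(expr1.values[gpos[k.feature_id]], expr1.bin_edges)
         - ec.onset_time(act.values[apos[k.feature_id]], act.bin_edges)
         for k in kin[:50] if k.access_lead_h > 0]
print(f"median (expression onset - accessibility onset) for pioneer-linked "
      f"genes: {np.median(leads):.2f} h (planted lead 0.5 h)")
# A positive median means chromatin opens before transcription starts,
# the signature of pioneer-factor action at 1-min resolution.
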