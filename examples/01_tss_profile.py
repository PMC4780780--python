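"""Profile CpG density around the TSS and measure the near-TSS enrichment.

Builds a synthetic genome whose promoters carry a known CpG
observed/expected ramp (background 0.6 rising 1.38x toward the TSS),
re-extracts the promoter windows from genome + annotation exactly as one
would from real FASTA/GFF3 inputs, and profiles CpG density as a 51-bp
moving average with observed/expected normalization.
"""

import numpy as np

import promotercpg as pc

cfg = pc.SyntheticGenomeConfig(n_genes=2000, seed=42)
ds = pc.simulate_dataset(cfg)
windows = pc.filter_full_upstream(
    [pc.extract_promoter_window(ds.genome, g) for g in ds.genes]
)
print(f"{len(windows)} of {len(ds.genes)} genes have the full 3 kb upstream domain")

profile = pc.profile_windows(windows, pc.ProfileConfig(normalization="obs_over_exp"))
for pos in (-2500, -1000, -100, 100):
    i = int(np.argmin(np.abs(profile.positions - pos)))
    print(
        f"position {profile.positions[i]:+5d}: CpG o/e = {profile.norm_density[i]:.3f} "
        f"(n = {profile.n_genes[i]} genes)"
    )

ratio = pc.tss_enrichment_ratio(profile, near=(-100, 0), background=(-3000, -2000))
print(f"TSS enrichment ratio (near [-100,0) vs background [-3000,-2000)): {ratio:.3f}")
print("-> the ratio recovers the generative 1.38x ramp; on real genomes it")
print("   measures how much CpG density rises toward the TSS over background.")
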