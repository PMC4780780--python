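"""Compare region-wise CpG frequencies across KEGG functional classes.

Promoters are split into four regions (+500..0, 0..-500, -500..-1000,
-1000..-3000 around the TSS) and each gene's raw CpG frequency per region
feeds a Kruskal-Wallis test across classes (Bonferroni over regions), with
Dunn's post-hoc letters where the omnibus test rejects. Here the
"Environmental Information Processing" class is simulated with 1.2x
elevated CpG in the far-upstream region, mimicking the kind of
class-specific shift the analysis is designed to flag.
"""

import promotercpg as pc

EIP = "Environmental Information Processing"
cfg = pc.SyntheticGenomeConfig(
    n_genes=1000,
    class_rho_offsets={EIP: (1.2, -3000, -1000)},
    multiclass_fraction=0.1,
    seed=21,
)
windows, genes = pc.simulate_windows(cfg)
assignment = {g.gene_id: g.kegg_classes for g in genes}
sets = pc.unique_class_sets(assignment)
print("unique-class gene counts:", {c: len(g) for c, g in sets.items()})

table = pc.region_frequency_table(windows)
for res in pc.class_region_analysis(table, sets, alpha=0.05):
    k = res.kruskal
    line = f"{res.region}: H = {k.statistic:6.2f}, adj p = {k.p_adjusted:.2e}"
    if res.significant:
        letters = ", ".join(f"{c.split()[0]}:{l}" for c, l in res.letters.items())
        line += f"  -> classes differ; letter groups {letters}"
    print(line)
print("-> regions sharing no letter differ significantly in CpG frequency;")
print("   only the far-upstream region (R4), where the offset was injected,")
print("   should separate the elevated class from the rest.")
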