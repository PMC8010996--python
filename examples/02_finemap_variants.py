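"""Fine-map a recessive QTL with carrier-compatible sequence variants.

Starting from a mapped top haplotype, infers each bull's carrier status
(0/1/2 copies), screens sequence variants within +/- 3 Mb for allele
frequencies compatible with complete linkage (> 0.8 in homozygous carriers,
0.4-0.6 in heterozygotes, < 0.05 in non-carriers), runs the recessive
variant association, and dissects the signal by conditioning on the lead
variant.
"""

import recqtl

cfg = recqtl.SimConfig(n_individuals=900, chrom_sizes=[1200, 800], seed=42)
panel = recqtl.simulate_panel(cfg)
causal = recqtl.embed_recessive_qtl(
    panel, "chr1", recqtl.Window("chr1", 301, 350), target_freq=0.18, seed=43
)
phenotypes = recqtl.simulate_fertility(panel, causal, beta_hom=-0.8, h2=0.1, seed=44)
variants, causal = recqtl.simulate_sequence_variants(panel, causal, seed=45)
pcs = recqtl.top_pcs(recqtl.compute_grm(panel), 10)

window = panel.with_bp(causal.window)
call = recqtl.HaplotypeCall(window, causal.allele_string, causal.realized_frequency, 0)
status = recqtl.carrier_status(panel, call)

compat = recqtl.compatibility_filter(
    variants, status, window.chrom,
    window.start_bp - 3_000_000, window.end_bp + 3_000_000,
)
n_compat = sum(r.compatible for r in compat)
print(f"{n_compat} of {len(compat)} regional variants compatible with "
      f"recessive inheritance of the top haplotype")

results, excluded = recqtl.variant_recessive_assoc(
    variants, phenotypes, pcs=pcs, maf_min=0.05, r2_min=0.4
)
ok = [r for r in results if r.status == "ok"]
best = min(ok, key=lambda r: r.p)
print(f"{len(excluded)} variants failed MAF/imputation filters")
print(f"lead variant {best.target}: p = {best.p:.3g}, effect {best.beta:+.2f} SD")

idx = variants.variant_ids.index(best.target)
conditional = (variants.dosages[idx] == 2).astype(float)
cond, _ = recqtl.variant_recessive_assoc(
    variants, phenotypes, pcs=pcs, conditional=conditional
)
remaining = min(r.p for r in cond if r.status == "ok" and r.target != best.target)
print(f"after conditioning on {best.target}: min regional p = {remaining:.3g}")
# Conditioning on the lead variant should leave no significant regional
# signal: the QTL is explained by a single recessive variant.
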