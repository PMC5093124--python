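"""Genotype synthetic products on a virtual gel and audit their labels.

Generates a 20-species panel and its multiplex, then a small cohort of
products — some correctly labeled, some with a related-species swap, an
omission or an unlisted addition — and reports the per-product claimed vs
detected categories and the cohort mislabeling summary.
"""

from probioplex import genotype as gt
from probioplex import primers, scheme, synth

panel = synth.generate_panel(synth.default_pgi_spec(seed=0))
assays = primers.design_panel_assays(panel)
plexed = scheme.partition_assays(assays, plex_size=5)
print(f"panel: {len(assays)} assays in {len(plexed.reactions)} reactions\n")

menus = [(), (), ("swap_related",), ("omit",), ("add",), ("swap_related", "add")]
rows = []
for i, menu in enumerate(menus):
    fx, sample_seqs = synth.generate_product_fixture(panel, menu, seed=10 + i,
                                                     product_id=f"P{i + 1}")
    calls = gt.genotype_sample(sample_seqs, plexed)
    row = gt.audit_against_label(calls, fx.label)
    rows.append(row)
    flagged = {t: c for t, c in row.categories.items()
               if c in (gt.CLAIMED_ABSENT, gt.UNCLAIMED_PRESENT)}
    print(f"{row.product_id}: injected={list(fx.injected_errors) or 'none'}")
    print(f"      discrepancies={flagged or 'none'}")

summary = gt.summarize_audit(gt.AuditMatrix(rows))
print(f"\ncohort: {summary['n_discrepant']}/{summary['n_products']} products "
      f"discrepant ({summary['pct_discrepant']}%), "
      f"{summary['pct_with_unclaimed']}% carry an unlisted species")
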