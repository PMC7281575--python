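"""Retention-time-aware pathway activity prediction on a planted signal.

A synthetic peak list is generated where every compound of one pathway is
perturbed (all its ion-form features significant).  Features are matched to
compounds over the adduct table, grouped into empirical compounds within an
RT window of 2% of the maximum retention time, and pathways are tested with
an EASE-corrected hypergeometric statistic smoothed by a permutation Gamma
null.
"""

import metaboflow as mf

feats, library, compounds, truth = mf.simulate_pathway_data(effect=1.0, seed=5)
params = mf.MummichogParams(ppm=10, p_cutoff=0.05, n_perm=100, seed=1)

matches = mf.match_mz(feats, compounds, params)
stages = mf.build_empirical_compounds(matches, feats, params)
print(f"{len(feats)} features, {len(matches)} (feature, compound, ion) matches")
print(f"RT window: {stages.window:.1f} s "
      f"(= 0.02 x max RT {feats['rt'].max():.0f} s)")
print(f"empirical compounds: {len(stages.initial)} initial -> "
      f"{len(stages.merged)} merged -> {len(stages.final)} with a primary ion")

rows = mf.enrich_mummichog(feats, library, compounds, params)
print(f"\n{'pathway':8s} {'hits':>6s} {'p_raw':>9s} {'p_gamma':>9s}")
for r in rows[:5]:
    print(f"{r.pathway:8s} {r.hits_sig:3d}/{r.total_ecs:<3d} {r.p_raw:9.2e} {r.p_gamma:9.2e}")
print(f"\nplanted pathway: {truth['enriched_pathway']} "
      f"(ranked {[r.pathway for r in rows].index(truth['enriched_pathway']) + 1})")
# The fully perturbed pathway is ranked first with a Gamma-adjusted p-value
# far below 0.05; the other pathways score near their null expectation.
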