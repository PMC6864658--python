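"""EJ versus non-EJ community comparison on a simulated network.

Runs the pooled Welch t-test and the pairwise rank-sum comparison twice:
once with no injected difference between environmental-justice and other
communities, once with a 2 ug/m3 shift, to show what the tests detect.
"""

from pmnet import spatial, synth


def compare(ej_effect, seed=8):
    config = synth.GeneratorConfig(seed=seed, ej_effect=ej_effect)
    sites = synth.make_sites(config)
    field = synth.simulate_regional_pm(config, sites=sites, hours=config.periods.hours("deployment"))
    ej = sites.loc[sites["ej_flag"], "site_id"].tolist()
    nonej = sites.loc[~sites["ej_flag"], "site_id"].tolist()
    series = {s: field[s] for s in field.columns}
    welch = spatial.group_test(series, ej, nonej, "welch_t")
    pairs = spatial.group_test(series, ej[:3], nonej[:3], "wilcoxon_rank", holm=True)
    return welch, pairs


for effect in (0.0, 2.0):
    welch, pairs = compare(effect)
    print(f"injected EJ effect {effect:+.1f} ug/m3:")
    print(f"  Welch t = {welch.statistic:+.2f}, p = {welch.p_value:.3g}, "
          f"mean difference = {welch.mean_difference:+.2f} ug/m3")
    sig = int((pairs["p_holm"] < 0.05).sum())
    print(f"  rank-sum site pairs significant after Holm: {sig} of {len(pairs)}")
    print()

print("With no injected effect the tests stay null; a 2 ug/m3 community")
print("shift is detected by both. The pooled Welch test treats hours as")
print("independent, so on strongly shared regional signal it is conservative.")
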