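"""End-to-end run: simulate, analyse, and summarise by biome × treatment.

Produces per-plant ΔT/β metrics, bootstrap 95 % CIs of the group means, a
fixed-effects Type III treatment×biome ANOVA, and Tukey–Kramer pairwise
contrasts.
"""

from thermoreg import RunConfig, run_pipeline

res = run_pipeline(RunConfig(simulate=True, seed=1))

dt = res.group_summaries.query("variable == 'delta_t_mean'")
print("grand-mean ΔT (°C) with bootstrap 95 % CI:")
for r in dt.itertuples(index=False):
    print(f"  {r.biome:9s} {r.treatment:6s} {r.mean:+.2f} [{r.ci_lo:+.2f}, {r.ci_hi:+.2f}]")

print("\nType III ANOVA, response ΔT:")
print(res.anova.query("response == 'delta_t_mean'").round(4).to_string(index=False))

sig = res.contrasts.query("response == 'delta_t_mean' and p_adj < 0.05")
print(f"\n{len(sig)} of {len(res.contrasts) // 2} pairwise ΔT contrasts significant (Tukey p < 0.05)")
print("\nLeaves cool below air under heat in the alpine/desert cohorts (negative ΔT),")
print("while temperate cohorts stay warmer than air — the generated contrast the")
print("pipeline is built to detect and quantify.")
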