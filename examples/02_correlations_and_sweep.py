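"""Screen the metrics against mean PCC and sweep the penalized-time constant.

Each primary metric is Pearson-correlated with per-worker mean PCC over
workers with at least 5 underlying data points; the Bonferroni flag uses
alpha = 0.05 over the 4 primary metrics. The c-sweep then recomputes PT
at 200 weighting constants in [0.05, 10.0] and asks whether any value
yields a significantly positive correlation.
"""

import crowdtrust as ct

study = ct.simulate_study(ct.SimulationConfig(seed=7))
pcc = ct.score_responses(study.responses, study.videos, study.classifier)
metrics, _ = ct.compute_all_metrics(study.responses, pcc, study.study_config)
table = ct.metrics_frame(metrics)

print("metric correlations with mean PCC:")
for res in ct.screen_metrics(table):
    flag = "  <- passes Bonferroni (p < 0.0125)" if res.passes_bonferroni else ""
    print(f"  {res.metric_name:12s} r = {res.r:+.2f}  p = {res.p_value:.2g}  "
          f"n = {res.n_workers}{flag}")

sweep = ct.sweep_pt_constant(study.responses, pcc, study.study_config)
verdict = "at least one" if sweep.any_positive else "no"
print(f"\nPT c-sweep over {len(sweep.c_values)} grid points "
      f"(n = {sweep.n_workers} workers): {verdict} c gives a significantly "
      "positive correlation")

time_res, dist_res = ct.postwarning_correlations(study.responses, pcc, study.study_config)
print("\npenalized-time ingredients vs mean PCC (warned workers only):")
print(f"  post-warning total time  r = {time_res.r:+.2f}  p = {time_res.p_value:.2g}  "
      f"n = {time_res.n_workers}")
print(f"  revision L1 distance     r = {dist_res.r:+.2f}  p = {dist_res.p_value:.2g}  "
      f"n = {dist_res.n_workers}")
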