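"""Score a simulated worker cohort and compute the four behavioral metrics.

Generates a synthetic study (60 workers rating 24 class-balanced videos,
13 ordinal questions each), scores every response through the ground-truth
logistic classifier, and prints each stage's summary. A worker's mean PCC
(probability of the correct class) is the performance criterion; MSCL1,
MPIL1, PT and mean time are the behavioral metrics meant to predict it
without any diagnostic ground truth.
"""

import crowdtrust as ct

study = ct.simulate_study(ct.SimulationConfig(seed=7))
print(f"{len(study.responses)} responses: {len(study.profiles)} workers x "
      f"{len(study.videos)} videos (plus retest ratings)")

pcc = ct.score_responses(study.responses, study.videos, study.classifier)
print(f"mean PCC across all ratings: {pcc['pcc'].mean():.3f}")

metrics, report = ct.compute_all_metrics(study.responses, pcc, study.study_config)
table = ct.metrics_frame(metrics)
print(f"\n{report['n_reported']} workers pass the >= "
      f"{study.study_config.min_videos_metrics}-video gate "
      f"({len(report['excluded'])} excluded)")
print("\nper-worker metric summary (NaN = metric undefined for that worker):")
print(table[["mscl1", "mpil1", "pt", "mean_time_s", "mean_pcc"]]
      .describe().loc[["mean", "std", "min", "max"]].round(2))

# MSCL1 needs a retest; PT needs a revision record after a warning
print(f"\nworkers with MSCL1 defined: {table['mscl1'].notna().sum()}, "
      f"with PT defined: {table['pt'].notna().sum()} — "
      "missingness itself tracks worker engagement")
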