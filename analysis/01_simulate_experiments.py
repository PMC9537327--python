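"""Generate both synthetic experiments and summarize their choice behavior.

Experiment 1: lags 0/+50/+83 ms crossed with metronome sound on/off,
14 participants x 15 blocks.  Experiment 2: signed lags -50..+50 ms plus a
delay-detection session in 17 ms steps.  Writes per-lag choice-probability
summaries under results/.
"""

from pathlib import Path

from fatiguelag import synthetic as syn
from fatiguelag.glmm import choice_table

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
SEED = 20

for exp_id, factory in ((1, syn.experiment1_config), (2, syn.experiment2_config)):
    cfg = factory(n_participants=14, blocks=15, seed=SEED)
    cohort, truth = syn.make_cohort(cfg, seed=SEED)
    trials = syn.build_dataset(cfg, cohort, truth, seed=SEED)
    rows = []
    for session in ("fatigue", "delay"):
        tab = choice_table(trials[trials["session"] == session])
        pooled = tab.groupby("lag_ms")["proportion"].agg(["mean", "sem"])
        pooled.insert(0, "session", session)
        rows.append(pooled.reset_index())
    import pandas as pd

    summary = pd.concat(rows, ignore_index=True)
    summary.insert(0, "experiment", exp_id)
    path = OUT / f"exp{exp_id}_choice_summary.csv"
    summary.to_csv(path, index=False)
    print(f"experiment {exp_id}: {len(trials)} trials")
    print(summary.to_string(index=False))
    print(f"-> {path}\n")
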