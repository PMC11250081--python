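"""Measure a temporal-order-judgment threshold with the ZEST staircase.

Simulates an observer whose true 75%-correct point is 60 ms and runs a
40-trial adaptive session: each trial is placed at the posterior-mean
threshold estimate, shortening the interval after correct answers and
lengthening it after errors.  The reported threshold is where the final
psychometric estimate crosses 75% correct.
"""

import numpy as np

import dystonia_screen as ds

observer = ds.gen_observer(threshold_ms=60.0, slope=3.0, lapse=0.0)
result, state = ds.run_session(observer, n_trials=40, seed=3)

soas = [t["soa_ms"] for t in state.trial_log]
marks = ["+" if t["correct"] else "-" for t in state.trial_log]
print("staircase (SOA in ms, + correct / - incorrect):")
for i in range(0, 40, 10):
    print("  " + "  ".join(f"{s:6.1f}{m}" for s, m in
                           zip(soas[i:i + 10], marks[i:i + 10])))
print(f"\nestimated threshold: {result.threshold_ms:.1f} ms "
      f"(true 75% point: 60 ms)")

estimates = [ds.run_session(observer, n_trials=40, seed=s)[0].threshold_ms
             for s in range(30)]
print(f"mean over 30 sessions: {np.mean(estimates):.1f} ms "
      f"(sd {np.std(estimates):.1f} ms) — single sessions scatter, the "
      f"session mean sits near the true threshold")
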