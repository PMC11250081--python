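"""From a recorded trial to the detector's input tensor.

Generates one synthetic healthy trial of the arpeggio-with-black-keys task
(60 Hz hand landmarks + 1 kHz key displacements), delimits the trial window
from the key kinematics, and time-normalizes the landmark segment to the
fixed 21 x 3 x 128 tensor the anomaly detector consumes.
"""

import dystonia_screen as ds

task = ds.TASKS[4]
traj, keys, meta = ds.gen_healthy_trial(task, seed=1, subject_id="H00")
print(f"trial: task {meta.task_id} ({task.name}), {meta.tempo_bpm} bpm, "
      f"{len(traj)} video frames, {len(keys)} key-trace samples")

window = ds.detect_trial_window(keys)
print(f"trial window from key kinematics: [{window.t_start:.3f}, "
      f"{window.t_end:.3f}] s ({window.duration:.2f} s of playing)")

segment = ds.extract_segment(traj, window)
tensor = ds.time_normalize(segment, meta=meta)
print(f"segment of {len(segment)} frames -> tensor {tensor.values.shape}")
print("the tensor rows are the 21 hand landmarks, columns the x/y/z "
      "coordinates, depth the 128 normalized time samples")
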