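# Epoch container format

`alphasep` reads and writes epoched EEG as plain HDF5. The schema is
deliberately minimal so any acquisition pipeline can target it.

## Schema

| dataset / attr            | type / shape                         | meaning |
|---------------------------|--------------------------------------|---------|
| `data`                    | float64, trials × channels × samples | signal (any consistent unit; power features come out in unit²/Hz) |
| `labels`                  | int64, trials                        | condition id per trial |
| `srate`                   | scalar float                         | sampling rate, Hz |
| `time_zero_s`             | scalar float                         | time of sample 0 relative to the alignment event, s |
| `channels`                | bytes, channels                      | channel labels, data order |
| attr `subject_id`         | string                               | subject identifier |
| `montage/channel_names`   | bytes                                | optional montage group |
| `montage/left_posterior`  | bytes                                | left MI electrode group |
| `montage/right_posterior` | bytes                                | right MI electrode group |
| `montage/stim_cluster`    | bytes                                | TMS stimulation cluster |
| `montage/channel_sides`   | bytes                                | per-channel left/right/midline |

Write with `alphasep.save_epochs(path, epochs, montage)`; read with
`alphasep.load_epochs(path)`.

## Converting vendor formats

Any reader that yields a trials × channels × samples array works. With
MNE-Python, for example:

```python
import mne
import numpy as np
from alphasep import EpochSet, Montage, save_epochs

mne_epochs = mne.read_epochs("subject01-epo.fif")
events = mne_epochs.events[:, 2]          # condition codes
epochs = EpochSet(
    data=mne_epochs.get_data(),           # trials x channels x samples
    srate=float(mne_epochs.info["sfreq"]),
    labels=events.astype(np.int64),
    channels=tuple(mne_epochs.ch_names),
    time_zero_s=float(mne_epochs.times[0]),
    subject_id="subject01",
)
montage = Montage(channel_names=tuple(mne_epochs.ch_names))  # default groups
save_epochs("subject01.h5", epochs, montage)
```

Condition labels are opaque integers to the pipeline except for the
left/right cue contrast: pass the attend-left and attend-right label values
to `modulation_index`, or follow the synthetic convention
(`alphasep.left_right_labels`).
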