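"""Readers and writers for the package's delimited text formats.

Two formats cover the experimental data:

* condition table -- one row per stimulus condition
  (``condition_id, direction, frequency_hz, contrast, duration_s,
  ramp_s, eccentricity_deg, aperture_sigma_deg, clipped``);
* spike raster -- one row per spike (``trial_id, condition_id,
  spike_time_s``), with a spike-less trial recorded as a row whose
  ``spike_time_s`` field is empty so that trial counts survive the
  round trip.

Both are tab-separated with a header row and round-trip losslessly
(spike times at full float precision).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from lgnsnr.snr import Trial, TrialSet
from lgnsnr.stimuli import ColorDirection, StimulusSpec

__all__ = [
    "write_conditions",
    "read_conditions",
    "write_rasters",
    "read_rasters",
]

_SEP = "\t"


def write_conditions(
    path: str | Path,
    schedule: dict[str, StimulusSpec],
    clipped: dict[str, bool] | None = None,
) -> None:
    """Write a condition table for ``schedule``."""
    rows = []
    for cid in sorted(schedule):
        spec = schedule[cid]
        rows.append(
            {
                "condition_id": cid,
                "direction": spec.color_direction.value,
                "frequency_hz": spec.temporal_frequency,
                "contrast": spec.cone_contrast,
                "duration_s": spec.duration,
                "ramp_s": spec.ramp,
                "eccentricity_deg": spec.eccentricity,
                "aperture_sigma_deg": spec.aperture_sigma,
                "clipped": bool(clipped.get(cid, False)) if clipped else False,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=_SEP, index=False)


def read_conditions(path: str | Path) -> tuple[dict[str, StimulusSpec], dict[str, bool]]:
    """Read a condition table back into specs and clipped flags."""
    df = pd.read_csv(path, sep=_SEP, dtype={"condition_id": str})
    schedule: dict[str, StimulusSpec] = {}
    clipped: dict[str, bool] = {}
    for _, row in df.iterrows():
        direction = ColorDirection.parse(row["direction"])
        schedule[row["condition_id"]] = StimulusSpec(
            color_direction=direction,
            temporal_frequency=float(row["frequency_hz"]),
            cone_contrast=float(row["contrast"]),
            duration=float(row["duration_s"]),
            ramp=float(row["ramp_s"]),
            eccentricity=float(row["eccentricity_deg"]),
            aperture_sigma=float(row["aperture_sigma_deg"]),
        )
        clipped[row["condition_id"]] = bool(row.get("clipped", False))
    return schedule, clipped


def write_rasters(path: str | Path, trial_set: TrialSet) -> None:
    """Write trial-aligned spike times; empty trials keep their row."""
    records: list[tuple[int, str, str]] = []
    for tr in trial_set.trials:
        if len(tr.spike_times) == 0:
            records.append((tr.trial_id, tr.condition_id, ""))
        else:
            for t in tr.spike_times:
                records.append((tr.trial_id, tr.condition_id, repr(float(t))))
    df = pd.DataFrame(records, columns=["trial_id", "condition_id", "spike_time_s"])
    df.to_csv(path, sep=_SEP, index=False)


def read_rasters(
    path: str | Path,
    conditions: dict[str, StimulusSpec],
    stim_on: float = 0.0,
    stim_off: float | None = None,
) -> TrialSet:
    """Read a spike raster file into a :class:`TrialSet`.

    ``stim_off`` defaults to the (shared) condition duration.
    """
    df = pd.read_csv(
        path, sep=_SEP, dtype={"condition_id": str}, float_precision="round_trip"
    )
    if stim_off is None:
        durations = {s.duration for s in conditions.values()}
        if len(durations) != 1:
            raise ValueError("pass stim_off explicitly: conditions differ in duration")
        stim_off = durations.pop()
    trials: list[Trial] = []
    for (trial_id, cid), grp in df.groupby(["trial_id", "condition_id"], sort=True):
        times = grp["spike_time_s"].dropna().to_numpy(dtype=float)
        trials.append(
            Trial(trial_id=int(trial_id), condition_id=cid, spike_times=np.sort(times))
        )
    trials.sort(key=lambda t: t.trial_id)
    return TrialSet(trials=trials, conditions=conditions, stim_on=stim_on, stim_off=stim_off)
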