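"""Plain-text / HDF5 persistence for simulated cohorts.

Layout written by :func:`write_cohort`::

    out/
      visits.csv            # one triage row per visit
      ground_truth.csv      # latent risk, events, onsets, true features
      vitals/<visit_id>.csv # 1-Hz channels + intermittent observations
      waveforms/<visit_id>.h5  # ECG/PPG sample arrays with fs attributes
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import yaml

from .synth import Cohort, SimConfig
from .types import VitalStream, WaveformSegment

__all__ = ["write_cohort", "read_vitals_csv", "read_waveform_pair",
           "sim_config_from_yaml"]


def sim_config_from_yaml(path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return SimConfig(**raw)


def write_cohort(
    cohort: Cohort,
    out_dir,
    max_streams: Optional[int] = None,
    write_waveforms: bool = True,
) -> Path:
    """Materialise a cohort to disk; returns the output directory.

    ``max_streams`` caps how many per-visit vitals/waveform files are
    written (tables are always complete) — streams regenerate from the
    seed, so persisting every one is rarely needed.
    """
    out = Path(out_dir)
    (out / "vitals").mkdir(parents=True, exist_ok=True)
    cohort.triage.to_csv(out / "visits.csv", index=False)
    cohort.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    ids = cohort.visit_ids if max_streams is None else cohort.visit_ids[:max_streams]
    for vid in ids:
        _vitals_to_csv(cohort.vitals[vid], out / "vitals" / f"{vid}.csv")
    if write_waveforms and cohort.waveforms is not None:
        (out / "waveforms").mkdir(exist_ok=True)
        for vid in ids:
            ecg, ppg = cohort.waveforms[vid]
            with h5py.File(out / "waveforms" / f"{vid}.h5", "w") as fh:
                for seg in (ecg, ppg):
                    ds = fh.create_dataset(seg.modality, data=seg.samples)
                    ds.attrs["fs"] = seg.fs
                    ds.attrs["start_time"] = seg.start_time
    return out


def _vitals_to_csv(stream: VitalStream, path) -> None:
    n = stream.duration_s
    df = pd.DataFrame(
        {
            "t_s": np.arange(n),
            "hr": stream.hr,
            "rr": stream.rr,
            "spo2": stream.spo2,
            "map": stream.map,
            "rr_interval": stream.rr_interval,
            "perfusion_index": stream.perfusion_index,
        }
    )
    obs = {
        "sbp": (stream.sbp_times, stream.sbp_values),
        "dbp": (stream.dbp_times, stream.dbp_values),
        "temperature": (stream.temperature_times, stream.temperature_values),
    }
    for name, (times, values) in obs.items():
        col = np.full(n, np.nan)
        idx = np.round(times).astype(int)
        ok = (idx >= 0) & (idx < n)
        col[idx[ok]] = np.asarray(values)[ok]
        df[name] = col
    df.to_csv(path, index=False, float_format="%.4f")


def read_vitals_csv(path) -> VitalStream:
    df = pd.read_csv(path)
    def _obs(col):
        ok = df[col].notna()
        return df.loc[ok, "t_s"].to_numpy(float), df.loc[ok, col].to_numpy(float)

    sbp_t, sbp_v = _obs("sbp")
    dbp_t, dbp_v = _obs("dbp")
    tmp_t, tmp_v = _obs("temperature")
    return VitalStream(
        hr=df["hr"].to_numpy(float),
        rr=df["rr"].to_numpy(float),
        spo2=df["spo2"].to_numpy(float),
        map=df["map"].to_numpy(float),
        rr_interval=df["rr_interval"].to_numpy(float),
        perfusion_index=df["perfusion_index"].to_numpy(float),
        sbp_times=sbp_t, sbp_values=sbp_v,
        dbp_times=dbp_t, dbp_values=dbp_v,
        temperature_times=tmp_t, temperature_values=tmp_v,
    )


def read_waveform_pair(path) -> tuple[WaveformSegment, WaveformSegment]:
    with h5py.File(path, "r") as fh:
        segs = {}
        for name in ("ecg", "ppg"):
            ds = fh[name]
            segs[name] = WaveformSegment(
                name, float(ds.attrs["fs"]), ds[...],
                float(ds.attrs["start_time"]),
            )
    return segs["ecg"], segs["ppg"]
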