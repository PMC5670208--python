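"""Plain-text readers and writers for the pipeline's tabular formats.

All formats are flat CSV/TSV so that datasets remain inspectable and
diff-able: blood datasets (continuous and discrete rows in one file), TACs
with their frame schedule, input functions, SCR traces and stimulus/event
tables, long-format ratings tables, and subject-record tables.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .frames import FrameSchedule
from .input_function import BloodDataset, InputFunction
from .kinetics import TissueTAC
from .scr import SCRTrace

__all__ = [
    "read_blood_csv", "write_blood_csv",
    "read_tac_csv", "write_tac_csv",
    "read_input_function_csv", "write_input_function_csv",
    "read_scr_tsv", "write_scr_tsv",
    "write_fit_report_json",
]


def write_blood_csv(path, blood: BloodDataset) -> None:
    cont = pd.DataFrame({"sample_type": "continuous",
                         "time_s": blood.continuous_time,
                         "whole_blood": blood.continuous_whole_blood,
                         "plasma": np.nan, "parent_fraction": np.nan})
    disc = pd.DataFrame({"sample_type": "discrete",
                         "time_s": blood.discrete_time * 60.0,
                         "whole_blood": blood.discrete_whole_blood,
                         "plasma": blood.discrete_plasma,
                         "parent_fraction": blood.discrete_parent_fraction})
    pd.concat([cont, disc]).to_csv(path, index=False)


def read_blood_csv(path) -> BloodDataset:
    df = pd.read_csv(path)
    cont = df[df["sample_type"] == "continuous"]
    disc = df[df["sample_type"] == "discrete"]
    return BloodDataset(cont["time_s"].to_numpy(),
                        cont["whole_blood"].to_numpy(),
                        disc["time_s"].to_numpy() / 60.0,
                        disc["plasma"].to_numpy(),
                        disc["whole_blood"].to_numpy(),
                        disc["parent_fraction"].to_numpy())


def write_tac_csv(path, tac: TissueTAC) -> None:
    pd.DataFrame({"frame_start_s": tac.schedule.frame_start,
                  "frame_dur_s": tac.schedule.frame_duration,
                  "activity": tac.activity,
                  "trues_rate": tac.schedule.trues_rate}).to_csv(path, index=False)


def read_tac_csv(path, region: str = "") -> TissueTAC:
    df = pd.read_csv(path)
    sched = FrameSchedule(df["frame_start_s"].to_numpy(),
                          df["frame_dur_s"].to_numpy(),
                          df["trues_rate"].to_numpy()
                          if "trues_rate" in df else None)
    return TissueTAC(sched, df["activity"].to_numpy(), region=region)


def write_input_function_csv(path, inp: InputFunction) -> None:
    pd.DataFrame({"time_s": inp.time,
                  "parent_plasma_activity": inp.parent_plasma_activity}
                 ).to_csv(path, index=False)


def read_input_function_csv(path) -> InputFunction:
    df = pd.read_csv(path)
    return InputFunction(df["time_s"].to_numpy(),
                         df["parent_plasma_activity"].to_numpy())


def write_scr_tsv(trace_path, trace: SCRTrace, events_path=None,
                  stimuli: pd.DataFrame | None = None) -> None:
    pd.DataFrame({"time_s": trace.time,
                  "conductance_uS": trace.conductance}
                 ).to_csv(trace_path, sep="\t", index=False)
    if events_path is not None and stimuli is not None:
        stimuli.to_csv(events_path, sep="\t", index=False)


def read_scr_tsv(trace_path) -> SCRTrace:
    df = pd.read_csv(trace_path, sep="\t")
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("SCR trace must be uniformly sampled")
    return SCRTrace(1.0 / dt[0], df["conductance_uS"].to_numpy())


def write_fit_report_json(path, **entries) -> None:
    """JSON report of fit parameters; numpy scalars/arrays are converted."""
    def _convert(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if hasattr(obj, "__dict__"):
            return {k: _convert(v) for k, v in vars(obj).items()
                    if not k.startswith("_")}
        if isinstance(obj, dict):
            return {k: _convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_convert(v) for v in obj]
        return obj
    with open(path, "w") as fh:
        json.dump({k: _convert(v) for k, v in entries.items()}, fh, indent=2)
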