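"""I_h sag metric for current-clamp recordings.

Hyperpolarization-activated HCN channels produce a depolarizing "sag" during
a sustained hyperpolarizing current step (here 5 s of -70 pA from -50 mV):
the voltage dips to a trough and then relaxes toward a steady level.  The
metric averages 5-10 sweeps pointwise and reports

    sag = V_steady - V_min,

where V_min is the most hyperpolarized point within the first second of the
stimulus and V_steady is the mean over a final steady-state window (last
500 ms of the stimulus by default).  A trace that relaxes upward after the
trough gives sag >= 0; a flat trace gives exactly 0; adding a constant
offset to the trace leaves the sag unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SweepSet", "average_sweeps", "compute_sag", "load_sweeps", "sag_from_sweeps"]


@dataclass(frozen=True)
class SweepSet:
    """Equal-length voltage sweeps (mV) on a uniform time base.

    sweeps: array of shape (n_sweeps, n_samples); dt: sampling interval (s);
    stimulus_onset / stimulus_duration in seconds from the trace start.
    """

    sweeps: np.ndarray
    dt: float
    stimulus_onset: float
    stimulus_duration: float = 5.0

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.sweeps, dtype=np.float64))
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 2:
            raise ValueError("need >= 1 sweep with >= 2 samples each")
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite voltage samples")
        if self.dt <= 0:
            raise ValueError("sampling interval must be > 0")
        if self.stimulus_onset < 0 or self.stimulus_duration <= 0:
            raise ValueError("invalid stimulus window")
        total = (arr.shape[1] - 1) * self.dt
        if self.stimulus_onset + self.stimulus_duration > total + 1e-9:
            raise ValueError(
                f"stimulus window [{self.stimulus_onset}, "
                f"{self.stimulus_onset + self.stimulus_duration}] s exceeds "
                f"trace duration {total:.6g} s"
            )
        object.__setattr__(self, "sweeps", arr)

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.sweeps.shape[1]) * self.dt


def average_sweeps(s: SweepSet) -> np.ndarray:
    """Pointwise arithmetic mean across sweeps."""
    if s.sweeps.shape[0] == 0:
        raise ValueError("empty sweep set")
    return s.sweeps.mean(axis=0)


def compute_sag(
    avg: np.ndarray,
    dt: float,
    stimulus_onset: float,
    stimulus_duration: float = 5.0,
    steady_window: float = 0.5,
    trough_window: float = 1.0,
) -> float:
    """Sag (mV) of an averaged trace: steady-state minus trough voltage.

    V_min is searched only within [onset, onset + trough_window] (first
    second by default); V_steady is the mean over the final
    ``steady_window`` seconds of the stimulus epoch.
    """
    avg = np.asarray(avg, dtype=np.float64)
    if avg.ndim != 1 or avg.size < 2:
        raise ValueError("average trace must be a 1D array with >= 2 samples")
    if dt <= 0:
        raise ValueError("sampling interval must be > 0")
    if steady_window <= 0 or trough_window <= 0:
        raise ValueError("windows must be > 0")
    if steady_window > stimulus_duration or trough_window > stimulus_duration:
        raise ValueError("window longer than the stimulus epoch")
    total = (avg.size - 1) * dt
    end = stimulus_onset + stimulus_duration
    if stimulus_onset < 0 or end > total + 1e-9:
        raise ValueError("stimulus window outside the trace")

    i0 = int(np.ceil(stimulus_onset / dt - 1e-9))
    i1 = int(np.floor((stimulus_onset + trough_window) / dt + 1e-9))
    v_min = float(avg[i0 : i1 + 1].min())
    j0 = int(np.ceil((end - steady_window) / dt - 1e-9))
    j1 = int(np.floor(end / dt + 1e-9))
    v_steady = float(avg[j0 : j1 + 1].mean())
    return v_steady - v_min


def sag_from_sweeps(s: SweepSet, steady_window: float = 0.5, trough_window: float = 1.0) -> float:
    """Average the sweeps, then compute the sag of the averaged trace."""
    return compute_sag(
        average_sweeps(s),
        s.dt,
        s.stimulus_onset,
        s.stimulus_duration,
        steady_window=steady_window,
        trough_window=trough_window,
    )


def load_sweeps(path, stimulus_onset: float, stimulus_duration: float = 5.0) -> SweepSet:
    """Read a CSV/TSV matrix: a time column named 't' or 'time' (seconds, or
    the first column), one column per sweep (mV)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    time_col = next((c for c in df.columns if c.lower() in ("t", "time")), df.columns[0])
    t = df[time_col].to_numpy(dtype=np.float64)
    if t.size < 2:
        raise ValueError(f"{path}: need >= 2 time samples")
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
        raise ValueError(f"{path}: non-uniform sampling interval")
    sweeps = df.drop(columns=[time_col]).to_numpy(dtype=np.float64).T
    return SweepSet(sweeps, float(dts[0]), stimulus_onset, stimulus_duration)
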