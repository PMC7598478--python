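"""Trajectory output, prevalence summaries, and the statistical validation harness."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model_core import Trajectory, TransitionRecord

__all__ = [
    "write_events",
    "read_events",
    "prevalence",
    "PrevalenceSeries",
    "ks_equivalence",
    "KSResult",
    "EventsFormatError",
]


class EventsFormatError(ValueError):
    """Malformed events file."""


_COUNTER_FIELDS = ("accepted", "rejected", "phi_evaluations",
                   "neighbor_lookups", "neighbor_regenerations")


def write_events(trajectory: Trajectory, path) -> None:
    """Write a trajectory as TSV: header, one transition per line, counter footer."""
    with open(path, "w") as fh:
        fh.write("time\tagent\tfrom_state\tto_state\n")
        for rec in trajectory.records:
            fh.write(f"{rec.time!r}\t{rec.agent}\t{rec.old_state}\t{rec.new_state}\n")
        fh.write(f"# engine={trajectory.engine}\n")
        fh.write(f"# horizon={trajectory.horizon!r}\n")
        for name in _COUNTER_FIELDS:
            fh.write(f"# {name}={getattr(trajectory, name)}\n")
        fh.write(f"# initial={','.join(trajectory.initial_state)}\n")


def read_events(path) -> Trajectory:
    """Read a trajectory written by :func:`write_events` (round-trip identity)."""
    records: List[TransitionRecord] = []
    meta: Dict[str, str] = {}
    last_time = -math.inf
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != ["time", "agent", "from_state", "to_state"]:
            raise EventsFormatError(f"line 1: unexpected header {header!r}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key] = val
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise EventsFormatError(f"line {lineno}: expected 4 columns")
            try:
                t = float(parts[0])
                agent = int(parts[1])
            except ValueError as exc:
                raise EventsFormatError(f"line {lineno}: bad time/agent") from exc
            if t <= last_time:
                raise EventsFormatError(
                    f"line {lineno}: non-increasing event time {t}")
            if parts[2] == parts[3]:
                raise EventsFormatError(
                    f"line {lineno}: transition does not change the state")
            last_time = t
            records.append(TransitionRecord(t, agent, parts[2], parts[3]))
    if "initial" not in meta or "horizon" not in meta:
        raise EventsFormatError("missing footer metadata (horizon/initial)")
    traj = Trajectory(engine=meta.get("engine", "?"),
                      horizon=float(meta["horizon"]),
                      initial_state=meta["initial"].split(","),
                      records=records)
    for name in _COUNTER_FIELDS:
        if name in meta:
            setattr(traj, name, int(meta[name]))
    return traj


# ---------------------------------------------------------------------------
# Prevalence
# ---------------------------------------------------------------------------

@dataclass
class PrevalenceSeries:
    """State fractions at probe times: per replica, plus ensemble mean/stderr."""

    probe_times: List[float]
    states: List[str]
    per_replica: np.ndarray  # shape (replicas, probes, states)

    @property
    def mean(self) -> np.ndarray:
        return self.per_replica.mean(axis=0)

    @property
    def stderr(self) -> np.ndarray:
        n = self.per_replica.shape[0]
        if n < 2:
            return np.zeros_like(self.mean)
        return self.per_replica.std(axis=0, ddof=1) / math.sqrt(n)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        mean, err = self.mean, self.stderr
        for i, t in enumerate(self.probe_times):
            for j, s in enumerate(self.states):
                rows.append({"time": t, "state": s,
                             "mean": mean[i, j], "stderr": err[i, j]})
        return pd.DataFrame(rows)


def prevalence(trajectories: Trajectory | Sequence[Trajectory],
               probe_times: Sequence[float],
               states: Sequence[str]) -> PrevalenceSeries:
    """State fractions at each probe time, replayed from the initial map.

    Accepts one trajectory or an ensemble; ensemble statistics (mean and
    standard error) are computed over replica-level fractions.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    out = np.empty((len(trajectories), len(probe_times), len(states)))
    for k, traj in enumerate(trajectories):
        for i, t in enumerate(probe_times):
            fr = traj.state_fractions(states, t)
            for j, s in enumerate(states):
                out[k, i, j] = fr[s]
    return PrevalenceSeries(list(map(float, probe_times)), list(states), out)


# ---------------------------------------------------------------------------
# Equivalence testing
# ---------------------------------------------------------------------------

class KSResult(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool


def ks_equivalence(ensemble_a: Sequence[float],
                   ensemble_b: Sequence[float]) -> KSResult:
    """Two-sample Kolmogorov–Smirnov test on replica-level statistics.

    Replicas are the i.i.d. unit: callers pass one scalar per replica
    (e.g. the infected fraction at the final probe time), never pooled
    events.  If both ensembles are a single identical constant the test is
    degenerate and ``p = 1`` is returned, flagged.
    """
    a = np.asarray(ensemble_a, dtype=float)
    b = np.asarray(ensemble_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ensembles must be non-empty")
    if np.unique(np.concatenate([a, b])).size == 1:
        return KSResult(0.0, 1.0, True)
    stat, p = sps.ks_2samp(a, b)
    return KSResult(float(stat), float(p), False)
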