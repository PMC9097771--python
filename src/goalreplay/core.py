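"""Core data containers shared by every analysis stage.

The study design these containers describe: a rat forages in a 2 m x 2 m
open arena whose floor holds a 6 x 6 grid of identical reward wells.  One
well is the session's Goal well; trials alternate between goal-seeking
(Goal well baited) and random-foraging (one of the 35 Random wells baited)
segments.  A session binds the position time series, per-unit spike trains,
LFP channels, the arena geometry and the trial schedule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

Segment = Literal["goal_seeking", "random_foraging"]


@dataclass(frozen=True)
class ArenaSpec:
    """Square open arena with an evenly spaced grid of reward wells.

    Wells are laid out on a ``wells_per_side`` x ``wells_per_side`` grid,
    centred in the arena: well *i* along an axis sits at
    ``(i + 0.5) * side_length / wells_per_side``, so the grid is inset by
    half a well spacing from each wall.  Well indices are row-major,
    0-based: ``index = row * wells_per_side + col``.
    """

    side_length: float = 200.0
    wells_per_side: int = 6
    goal_well: int = 0

    def __post_init__(self) -> None:
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")
        if self.wells_per_side < 2:
            raise ValueError("wells_per_side must be >= 2")
        if not 0 <= self.goal_well < self.n_wells:
            raise ValueError(f"goal_well must be in [0, {self.n_wells})")

    @property
    def n_wells(self) -> int:
        return self.wells_per_side**2

    @property
    def well_spacing(self) -> float:
        return self.side_length / self.wells_per_side

    @property
    def well_positions(self) -> np.ndarray:
        """(n_wells, 2) array of well centres [cm], row-major order."""
        s = self.well_spacing
        coords = (np.arange(self.wells_per_side) + 0.5) * s
        xx, yy = np.meshgrid(coords, coords, indexing="xy")
        return np.column_stack([xx.ravel(), yy.ravel()])

    def goal_adjacent_wells(self, well: int | None = None) -> np.ndarray:
        """Indices of the up-to-8 grid neighbours of ``well`` (default Goal)."""
        if well is None:
            well = self.goal_well
        n = self.wells_per_side
        r, c = divmod(well, n)
        out = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < n and 0 <= cc < n:
                    out.append(rr * n + cc)
        return np.asarray(out, dtype=int)

    def to_dict(self) -> dict:
        return {
            "side_length": self.side_length,
            "wells_per_side": self.wells_per_side,
            "goal_well": self.goal_well,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaSpec":
        return cls(**d)


def make_arena(side_length: float = 200.0, wells_per_side: int = 6,
               goal_well: int = 0) -> ArenaSpec:
    """Build an :class:`ArenaSpec` with an evenly spaced, centred well grid."""
    return ArenaSpec(side_length=side_length, wells_per_side=wells_per_side,
                     goal_well=goal_well)


@dataclass(frozen=True)
class TrialRecord:
    index: int
    segment: Segment
    target_well: int
    start_time: float
    end_time: float

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


class TrialSchedule:
    """Ordered, contiguous, strictly alternating trial records.

    Segments alternate goal_seeking / random_foraging starting with
    goal_seeking; no Random well repeats within 15 consecutive trials.
    """

    def __init__(self, trials: list[TrialRecord]):
        self._check(trials)
        self.trials = list(trials)

    @staticmethod
    def _check(trials: list[TrialRecord]) -> None:
        for i, t in enumerate(trials):
            if t.end_time < t.start_time:
                raise ValueError(f"trial {i}: end before start")
            expect = "goal_seeking" if i % 2 == 0 else "random_foraging"
            if t.segment != expect:
                raise ValueError(f"trial {i}: expected segment {expect}")
            if i and abs(t.start_time - trials[i - 1].end_time) > 1e-9:
                raise ValueError(f"trial {i}: not contiguous")
        rand = [(i, t.target_well) for i, t in enumerate(trials)
                if t.segment == "random_foraging"]
        for j, (i, w) in enumerate(rand):
            for i2, w2 in rand[j + 1:]:
                if i2 - i < 15 and w2 == w:
                    raise ValueError(
                        f"Random well {w} repeats within 15 trials ({i}, {i2})")

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, i: int) -> TrialRecord:
        return self.trials[i]

    @property
    def span(self) -> tuple[float, float]:
        return self.trials[0].start_time, self.trials[-1].end_time

    def trial_at(self, t: float) -> int | None:
        """Trial index containing time ``t`` (half-open [start, end))."""
        for tr in self.trials:
            if tr.start_time <= t < tr.end_time:
                return tr.index
        if self.trials and t == self.trials[-1].end_time:
            return self.trials[-1].index
        return None

    def trial_of_times(self, times: np.ndarray) -> np.ndarray:
        """Vectorised trial lookup; -1 outside the schedule span."""
        times = np.asarray(times, dtype=float)
        starts = np.array([tr.start_time for tr in self.trials])
        ends = np.array([tr.end_time for tr in self.trials])
        idx = np.searchsorted(starts, times, side="right") - 1
        idx = np.clip(idx, 0, len(self.trials) - 1)
        out = np.array([self.trials[i].index for i in idx])
        bad = (times < starts[0]) | (times > ends[-1])
        out = np.where(bad, -1, out)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": [t.index for t in self.trials],
                "segment": [t.segment for t in self.trials],
                "target_well": [t.target_well for t in self.trials],
                "start_time": [t.start_time for t in self.trials],
                "end_time": [t.end_time for t in self.trials],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialSchedule":
        trials = [
            TrialRecord(int(r.trial), str(r.segment), int(r.target_well),
                        float(r.start_time), float(r.end_time))
            for r in df.itertuples()
        ]
        return cls(trials)


@dataclass
class SessionData:
    """A complete recording session.

    position: DataFrame with columns t [s], x [cm], y [cm] (default 60 Hz)
    spikes:   list of sorted spike-time arrays [s], one per unit
    unit_class: per-unit label, "excitatory" or "inhibitory"
    lfp:      (n_samples, n_channels) array sampled at ``lfp_rate`` Hz
    lfp_t:    sample times [s]
    """

    position: pd.DataFrame
    spikes: list[np.ndarray]
    unit_class: list[str]
    lfp: np.ndarray
    lfp_t: np.ndarray
    lfp_rate: float
    arena: ArenaSpec
    schedule: TrialSchedule
    seed: int = 0
    ground_truth: "object | None" = field(default=None, repr=False)

    @property
    def n_units(self) -> int:
        return len(self.spikes)

    @property
    def excitatory(self) -> np.ndarray:
        return np.array([c == "excitatory" for c in self.unit_class])

    # -- serialization: directory of plain-text CSV/JSON files -------------
    def to_dir(self, path: str | Path, float_fmt: str = "%.6f") -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.position.to_csv(path / "position.csv", index=False,
                             float_format=float_fmt)
        rows = [(u, t) for u, st in enumerate(self.spikes) for t in st]
        pd.DataFrame(rows, columns=["unit", "t"]).to_csv(
            path / "spikes.csv", index=False, float_format=float_fmt)
        lfp_df = pd.DataFrame({"t": self.lfp_t})
        for c in range(self.lfp.shape[1]):
            lfp_df[f"ch{c}"] = self.lfp[:, c]
        lfp_df.to_csv(path / "lfp.csv", index=False, float_format="%.4f")
        self.schedule.to_frame().to_csv(path / "schedule.csv", index=False,
                                        float_format=float_fmt)
        meta = {
            "arena": self.arena.to_dict(),
            "seed": int(self.seed),
            "lfp_rate": float(self.lfp_rate),
            "unit_class": list(self.unit_class),
        }
        (path / "arena.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_dir(cls, path: str | Path) -> "SessionData":
        path = Path(path)
        meta = json.loads((path / "arena.json").read_text())
        pos = pd.read_csv(path / "position.csv")
        spk = pd.read_csv(path / "spikes.csv")
        n_units = len(meta["unit_class"])
        spikes = [np.sort(spk.loc[spk.unit == u, "t"].to_numpy())
                  for u in range(n_units)]
        lfp_df = pd.read_csv(path / "lfp.csv")
        chans = [c for c in lfp_df.columns if c.startswith("ch")]
        return cls(
            position=pos,
            spikes=spikes,
            unit_class=meta["unit_class"],
            lfp=lfp_df[chans].to_numpy(),
            lfp_t=lfp_df["t"].to_numpy(),
            lfp_rate=float(meta["lfp_rate"]),
            arena=ArenaSpec.from_dict(meta["arena"]),
            schedule=TrialSchedule.from_frame(pd.read_csv(path / "schedule.csv")),
            seed=int(meta["seed"]),
        )

    def position_at(self, times: np.ndarray) -> np.ndarray:
        """Linear-interpolated (x, y) at arbitrary times."""
        t = self.position["t"].to_numpy()
        x = np.interp(times, t, self.position["x"].to_numpy())
        y = np.interp(times, t, self.position["y"].to_numpy())
        return np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])
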