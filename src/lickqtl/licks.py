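"""Lick microstructure phenotypes from lickometer event streams.

A lickometer records the time of each tongue contact to the nearest ms.
Successive contacts define inter-lick intervals (ILIs); in mice most ILIs
fall in a "primary" band of roughly 50-160 ms reflecting the rhythm of the
brainstem licking pattern generator, with longer intervals corresponding to
pauses between drinking bursts.  The phenotypes extracted here are:

* MPI - mean primary inter-lick interval: the mean of ILIs inside the
  primary window (bounds inclusive).  Lower MPI = faster licking.
* total licks - contact count per session.
* VPL - volume per lick: spillage-corrected volume (mL) divided by total
  licks, reported in uL/lick.

Sessions with no in-window ILI yield an undefined (NaN) MPI, never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PRIMARY_WINDOW = (50.0, 160.0)  # ms, inclusive bounds


@dataclass
class LickEventStream:
    """One lickometer session: ordered contact timestamps plus metadata."""

    session_id: str
    timestamps: np.ndarray  # ms since session start, strictly increasing
    animal: str = ""
    strain: str = ""
    sex: str = ""
    day: int = 0
    stimulus: str = ""
    body_weight_g: float = float("nan")
    volume_ml: float = float("nan")
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=np.int64)
        if t.size and t[0] < 0:
            raise ValueError(f"session {self.session_id}: negative timestamp")
        if t.size > 1 and not (np.diff(t) > 0).all():
            raise ValueError(
                f"session {self.session_id}: timestamps not strictly increasing"
            )
        self.timestamps = t

    @property
    def n_licks(self) -> int:
        return int(self.timestamps.size)


@dataclass(frozen=True)
class ILIDistribution:
    """Fixed-width ILI histogram over [0, upper) with half-open bins."""

    bin_edges: np.ndarray  # len = n_bins + 1
    counts: np.ndarray  # per-bin counts of ILIs < upper
    n_total: int  # all ILIs, including those >= upper


def parse_sessions(
    sessions_file: str | Path, events_file: str | Path
) -> list[LickEventStream]:
    """Read ``sessions.csv`` + ``events.csv`` into one stream per session.

    sessions.csv needs columns session_id, animal_id, strain, sex, day,
    stimulus, body_weight_g (volume_ml optional); events.csv needs
    session_id, t_ms.  Events are sorted by time within session; duplicate
    or negative timestamps and events referencing unknown sessions are
    errors naming the offending session.
    """
    sessions = pd.read_csv(sessions_file, dtype={"session_id": str})
    events = pd.read_csv(events_file, dtype={"session_id": str})

    required = ["session_id", "animal_id", "strain", "sex", "day",
                "stimulus", "body_weight_g"]
    missing = [c for c in required if c not in sessions.columns]
    if missing:
        raise ValueError(f"sessions file missing columns: {missing}")
    missing = [c for c in ("session_id", "t_ms") if c not in events.columns]
    if missing:
        raise ValueError(f"events file missing columns: {missing}")

    known = set(sessions["session_id"])
    orphan = set(events["session_id"]) - known
    if orphan:
        raise ValueError(f"events reference unknown sessions: {sorted(orphan)[:5]}")

    by_session = {sid: grp["t_ms"].to_numpy() for sid, grp in
                  events.groupby("session_id", sort=False)}
    streams = []
    for _, row in sessions.iterrows():
        sid = row["session_id"]
        t = np.sort(by_session.get(sid, np.empty(0, dtype=np.int64)))
        streams.append(
            LickEventStream(
                session_id=sid,
                timestamps=t,
                animal=str(row["animal_id"]),
                strain=str(row["strain"]),
                sex=str(row["sex"]),
                day=int(row["day"]),
                stimulus=str(row["stimulus"]),
                body_weight_g=float(row["body_weight_g"]),
                volume_ml=float(row["volume_ml"]) if "volume_ml" in row.index
                and pd.notna(row["volume_ml"]) else float("nan"),
            )
        )
    return streams


def compute_ilis(stream: LickEventStream) -> np.ndarray:
    """Successive timestamp differences in ms (length n_licks - 1)."""
    if stream.n_licks < 2:
        return np.empty(0, dtype=np.int64)
    return np.diff(stream.timestamps)


def ili_histogram(
    ilis: np.ndarray, bin_width: float = 5.0, upper: float = 250.0
) -> ILIDistribution:
    """Histogram ILIs into half-open bins [k*w, (k+1)*w) covering [0, upper).

    ILIs >= upper are excluded from the counts but included in ``n_total``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    ilis = np.asarray(ilis, dtype=float)
    edges = np.arange(0.0, upper + bin_width / 2, bin_width)
    in_range = ilis[ilis < upper]
    counts, _ = np.histogram(in_range, bins=edges)
    return ILIDistribution(bin_edges=edges, counts=counts, n_total=int(ilis.size))


def compute_mpi(
    ilis: np.ndarray, window: tuple[float, float] = PRIMARY_WINDOW
) -> float:
    """Mean of ILIs inside the primary window (inclusive bounds), in ms.

    Returns NaN when no ILI falls in the window — the phenotype is
    undefined for that session, not zero.
    """
    lo, hi = window
    if lo >= hi:
        raise ValueError("window bounds must satisfy lo < hi")
    ilis = np.asarray(ilis, dtype=float)
    primary = ilis[(ilis >= lo) & (ilis <= hi)]
    if primary.size == 0:
        return float("nan")
    return float(primary.mean())


def compute_vpl(volume_consumed_ml: float, total_licks: int) -> float:
    """Volume per lick in uL/lick: 1000 * volume / licks.

    Undefined (NaN) when no licks were recorded; volume must be the
    spillage-corrected value measured upstream.
    """
    if total_licks <= 0:
        return float("nan")
    if volume_consumed_ml < 0:
        raise ValueError("volume must be non-negative")
    return 1000.0 * volume_consumed_ml / total_licks


def reject_outliers(
    values, k: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass +/- k*SD rejection.

    Mean and sample SD are computed once over all defined (non-NaN) values;
    values with |v - mean| strictly greater than k*SD are rejected (a value
    exactly at the boundary is retained).  NaN entries are passed through
    untouched.  Returns (retained values, rejected indices into the input).
    """
    v = np.asarray(values, dtype=float)
    defined = np.flatnonzero(~np.isnan(v))
    if defined.size < 2:
        raise ValueError("need >= 2 defined values for outlier rejection")
    sample = v[defined]
    mean = sample.mean()
    sd = sample.std(ddof=1)
    reject_mask = np.zeros(v.size, dtype=bool)
    if sd > 0:
        reject_mask[defined] = np.abs(sample - mean) > k * sd
    rejected = np.flatnonzero(reject_mask)
    retained = v[~reject_mask]
    return retained, rejected


def build_phenotypes(
    streams: list[LickEventStream],
    window: tuple[float, float] = PRIMARY_WINDOW,
    reject_sd: float = 3.0,
) -> pd.DataFrame:
    """One phenotype row per session: MPI, total licks, volume, VPL.

    VPL outliers are rejected per stimulus across all animals in a single
    pass at +/- reject_sd SD (set to NaN, flagged in ``vpl_rejected``);
    undefined phenotypes are NaN with the reason in ``flags``.
    """
    rows = []
    for s in streams:
        ilis = compute_ilis(s)
        mpi = compute_mpi(ilis, window) if ilis.size else float("nan")
        vpl = (compute_vpl(s.volume_ml, s.n_licks)
               if np.isfinite(s.volume_ml) else float("nan"))
        flags = []
        if np.isnan(mpi):
            flags.append("mpi_undefined")
        if np.isnan(vpl):
            flags.append("vpl_undefined")
        rows.append({
            "session_id": s.session_id, "animal": s.animal, "strain": s.strain,
            "sex": s.sex, "day": s.day, "stimulus": s.stimulus,
            "body_weight_g": s.body_weight_g, "total_licks": s.n_licks,
            "volume_ml": s.volume_ml, "mpi": mpi, "vpl": vpl,
            "flags": ";".join(flags),
        })
    df = pd.DataFrame(rows)
    df["vpl_rejected"] = False
    if reject_sd is not None and len(df):
        for _, idx in df.groupby("stimulus").groups.items():
            vals = df.loc[idx, "vpl"].to_numpy()
            if np.sum(~np.isnan(vals)) >= 2:
                _, rej = reject_outliers(vals, k=reject_sd)
                rej_idx = np.asarray(idx)[rej]
                df.loc[rej_idx, "vpl_rejected"] = True
                df.loc[rej_idx, "vpl"] = np.nan
    return df


def strain_means(
    phenotypes: pd.DataFrame,
    traits: tuple[str, ...] = ("mpi", "total_licks", "vpl"),
    include_training_day: bool = False,
) -> pd.DataFrame:
    """Long-format per-strain summaries: strain, stimulus, trait, mean, sem, n.

    Day-1 sessions are a training day (low, unstable licking) and are
    excluded from summaries used for mapping unless requested.
    """
    df = phenotypes
    if not include_training_day and "day" in df.columns:
        df = df[df["day"] != 1]
    out = []
    for (strain, stim), grp in df.groupby(["strain", "stimulus"]):
        for trait in traits:
            vals = grp[trait].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            sem = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
            out.append({"strain": strain, "stimulus": stim, "trait": trait,
                        "mean": vals.mean(), "sem": sem, "n": vals.size})
    return pd.DataFrame(out)
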