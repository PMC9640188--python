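"""Classification of chromosome-segregation errors from anaphase trajectories.

Three error classes are distinguished among tracked kinetochore pairs:

* **misaligned** — both sisters sit outside the metaphase-plate slab 30 s
  before anaphase onset;
* **lagging** — during anaphase one punctum is stretched (elongation above a
  threshold) while stalled in the central part of the spindle, outside the
  poleward-moving kinetochore masses;
* **other** — remaining anomalies: pairs that never separate, or central
  non-stretched stragglers.

Precedence is misaligned > lagging > other.  Missegregation is scored at the
final frame: a misaligned pair missegregates when both sisters end nearer the
same pole; a lagging pair when its stretched sister ends nearer the pole
opposite its pre-onset side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DependencyError, InvalidParameterError
from .kc_geometry import Region


@dataclass
class ClassifierParams:
    """Thresholds of the rule-based classifier.

    stretch_threshold: punctum major/minor axis ratio above which a CENP-A
    signal counts as "visibly stretched" (default 1.5).  central_fraction:
    half-width of the "central part of the spindle" as a fraction of the
    pole-to-pole span (default 1/6, i.e. the middle third).
    plate_half_thickness: metaphase-plate slab half-thickness in µm; when
    None it is estimated robustly (3 × 1.4826 × MAD, floor 1 µm) from the
    kinetochore x-distribution 30 s before onset.  lookback_s: how long
    before onset the plate criterion is evaluated.  unseparated_threshold:
    final interkinetochore distance below which a pair counts as never
    having separated.
    """

    stretch_threshold: float = 1.5
    central_fraction: float = 1.0 / 6.0
    plate_half_thickness: float | None = None
    lookback_s: float = 30.0
    unseparated_threshold: float = 2.0


@dataclass
class ErrorRecord:
    pair_id: int
    error_class: str                 # misaligned | lagging | other | none
    missegregated: bool | None
    region_at_onset: Region | None
    tilt_at_onset: float | None
    interkc_at_onset: float | None


def _pair_frames(traj: pd.DataFrame, pair_id):
    sub = traj[(traj["object"] == "kinetochore") & (traj["track_id"] == pair_id)]
    s1 = sub[sub["sister"] == 1].sort_values("frame")
    s2 = sub[sub["sister"] == 2].sort_values("frame")
    if len(s1) == 0 or len(s2) == 0 or len(s1) != len(s2):
        raise InvalidParameterError(f"incomplete sister tracks for pair {pair_id}")
    return s1.reset_index(drop=True), s2.reset_index(drop=True)


def _poles(traj: pd.DataFrame):
    poles = traj[traj["object"] == "pole"]
    if set(poles["track_id"].unique()) < {"pole_A", "pole_B"}:
        raise DependencyError("missing pole track (need pole_A and pole_B)")
    pa = poles[poles["track_id"] == "pole_A"].sort_values("frame").reset_index(drop=True)
    pb = poles[poles["track_id"] == "pole_B"].sort_values("frame").reset_index(drop=True)
    return pa, pb


def _xyz(df: pd.DataFrame, idx) -> np.ndarray:
    return df.loc[idx, ["x", "y", "z"]].to_numpy(dtype=float)


def estimate_plate_model(traj: pd.DataFrame, frame: int) -> tuple[float, float]:
    """Plate centre and slab half-thickness from the pair-midpoint
    distribution along the spindle axis at one frame.

    Midpoints rather than sister positions: the sister x-offset (half the
    interkinetochore distance) would otherwise inflate the plate thickness.
    Robust scale (median, 2.5 × scaled MAD, floored at 1 µm) so displaced
    pairs do not widen their own acceptance slab.
    """
    kc = traj[(traj["object"] == "kinetochore") & (traj["frame"] == frame)]
    if len(kc) == 0:
        raise DependencyError(f"no kinetochores at frame {frame}")
    x = kc.groupby("track_id")["x"].mean().to_numpy(dtype=float)
    center = float(np.median(x))
    mad = float(np.median(np.abs(x - center)))
    half = max(2.5 * 1.4826 * mad, 1.0)
    return center, half


def _lookback_frame(traj: pd.DataFrame, onset: int, lookback_s: float) -> int:
    """Nearest acquired frame to (onset time − lookback)."""
    frames = traj[["frame", "time_s"]].drop_duplicates().sort_values("frame")
    t_onset = float(frames.loc[frames["frame"] == onset, "time_s"].iloc[0])
    target = t_onset - lookback_s
    i = (frames["time_s"] - target).abs().idxmin()
    return int(frames.loc[i, "frame"])


def classify_pair(
    traj: pd.DataFrame,
    pair_id,
    onset: int,
    params: ClassifierParams | None = None,
    plate: tuple[float, float] | None = None,
) -> ErrorRecord:
    """Classify one kinetochore pair from the full-cell trajectory table."""
    params = params or ClassifierParams()
    s1, s2 = _pair_frames(traj, pair_id)
    pa, pb = _poles(traj)
    n_frames = len(s1)
    if onset >= n_frames:
        raise InvalidParameterError("onset beyond trajectory length")

    look = _lookback_frame(traj, onset, params.lookback_s)
    if plate is None:
        center, half = estimate_plate_model(traj, look)
    else:
        center, half = plate
    if params.plate_half_thickness is not None:
        half = params.plate_half_thickness

    sep = np.linalg.norm(
        s1[["x", "y", "z"]].to_numpy() - s2[["x", "y", "z"]].to_numpy(), axis=1
    )
    interkc_at_onset = float(sep[onset])

    # --- misaligned: both sisters outside the plate slab at onset - 30 s
    x1, x2 = float(s1.loc[look, "x"]), float(s2.loc[look, "x"])
    misaligned = abs(x1 - center) > half and abs(x2 - center) > half

    # --- lagging: a stretched punctum stalled centrally during anaphase
    lagging = False
    other_straggler = False
    post = range(onset + 1, n_frames)
    for f in post:
        pole_ax = float(pa.loc[f, "x"])
        pole_bx = float(pb.loc[f, "x"])
        span = pole_bx - pole_ax
        mid = 0.5 * (pole_ax + pole_bx)
        central_half = abs(span) * params.central_fraction
        for s in (s1, s2):
            xs = float(s.loc[f, "x"])
            if abs(xs - mid) < central_half:
                if float(s.loc[f, "elongation"]) > params.stretch_threshold:
                    lagging = True
                elif f >= onset + max((n_frames - onset) // 2, 2) and sep[f] > params.unseparated_threshold:
                    # separated, central, late, but not stretched
                    other_straggler = True

    never_separated = float(sep[-1]) < params.unseparated_threshold

    if misaligned:
        klass = "misaligned"
    elif lagging:
        klass = "lagging"
    elif never_separated or other_straggler:
        klass = "other"
    else:
        klass = "none"

    misseg = None
    if klass in ("misaligned", "lagging"):
        misseg = missegregation_outcome(traj, pair_id, klass, onset, params)

    return ErrorRecord(
        pair_id=pair_id,
        error_class=klass,
        missegregated=misseg,
        region_at_onset=None,
        tilt_at_onset=None,
        interkc_at_onset=interkc_at_onset,
    )


def missegregation_outcome(
    traj: pd.DataFrame,
    pair_id,
    error_class: str,
    onset: int,
    params: ClassifierParams | None = None,
) -> bool | None:
    """Score the segregation outcome of an erroneous pair at the final frame.

    Returns True (missegregated), False (correct), or None when the nearest
    pole is ambiguous (equidistant).
    """
    params = params or ClassifierParams()
    s1, s2 = _pair_frames(traj, pair_id)
    pa, pb = _poles(traj)
    last = len(s1) - 1

    def nearer_pole(sister_df, frame):
        p = _xyz(sister_df, frame)
        da = np.linalg.norm(p - _xyz(pa, frame))
        db = np.linalg.norm(p - _xyz(pb, frame))
        if np.isclose(da, db):
            return None
        return "A" if da < db else "B"

    if error_class == "misaligned":
        n1, n2 = nearer_pole(s1, last), nearer_pole(s2, last)
        if n1 is None or n2 is None:
            return None
        return n1 == n2
    if error_class == "lagging":
        # the stretched sister: highest elongation over the anaphase frames
        e1 = s1.loc[onset + 1 :, "elongation"].max()
        e2 = s2.loc[onset + 1 :, "elongation"].max()
        lag = s1 if e1 >= e2 else s2
        look = _lookback_frame(traj, onset, params.lookback_s)
        center, _ = estimate_plate_model(traj, look)
        pre_side = "A" if float(lag.loc[look, "x"]) < center else "B"
        final = nearer_pole(lag, last)
        if final is None:
            return None
        return final != pre_side
    return None


def classify_cell(
    traj: pd.DataFrame,
    onset: int,
    params: ClassifierParams | None = None,
) -> pd.DataFrame:
    """Classify every kinetochore pair of one cell; returns an ErrorRecord
    table (pair_id, error_class, missegregated, interkc_at_onset)."""
    params = params or ClassifierParams()
    look = _lookback_frame(traj, onset, params.lookback_s)
    plate = estimate_plate_model(traj, look)
    pair_ids = sorted(
        traj.loc[traj["object"] == "kinetochore", "track_id"].unique()
    )
    records = [classify_pair(traj, pid, onset, params, plate=plate) for pid in pair_ids]
    return pd.DataFrame(
        [
            dict(
                pair_id=r.pair_id,
                error_class=r.error_class,
                missegregated=r.missegregated,
                interkc_at_onset=r.interkc_at_onset,
            )
            for r in records
        ]
    )


def error_census(records_per_cell: dict) -> dict:
    """Aggregate classified records across cells.

    ``records_per_cell`` maps cell id -> ErrorRecord DataFrame.  Returns
    per-class mean ± SEM error counts per cell and missegregation fractions.
    """
    if not records_per_cell:
        raise InvalidParameterError("need records for at least one cell")
    classes = ("misaligned", "lagging", "other")
    counts = {k: [] for k in classes}
    totals = []
    missegregated = {k: 0 for k in classes}
    class_n = {k: 0 for k in classes}
    for df in records_per_cell.values():
        err = df[df["error_class"] != "none"]
        totals.append(len(err))
        for k in classes:
            sub = df[df["error_class"] == k]
            counts[k].append(len(sub))
            class_n[k] += len(sub)
            missegregated[k] += int(sub["missegregated"].fillna(False).sum())

    def mean_sem(vals):
        v = np.asarray(vals, dtype=float)
        sem = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        return float(v.mean()), sem

    out = {"errors_per_cell": dict(zip(("mean", "sem"), mean_sem(totals)))}
    for k in classes:
        m, s = mean_sem(counts[k])
        out[f"{k}_per_cell"] = {"mean": m, "sem": s}
        out[f"fraction_missegregating_{k}"] = (
            missegregated[k] / class_n[k] if class_n[k] else np.nan
        )
    return out
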