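"""TT-TG distance: signed separation of tuberosity and trochlear groove along
the posterior condylar axis, plus per-specimen and cohort delta tables.

The tibial tuberosity (TTP) and trochlear groove centre (TGCP) are orthogonally
projected onto the posterior condylar axis (the line FMCP–FLCP); the TT-TG
distance is the signed separation of the two projections.  With the axis
oriented medial-to-lateral (right-knee convention), positive values mean a
lateralised tuberosity — the clinical sign convention.

Projecting the raw 3D points is equivalent to first flattening them into the
axial (XY) plane spanned by FMCP/FLCP/TGCP and projecting in-plane: the
flattening removes only components orthogonal to the condylar axis, which the
projection discards anyway.  The equivalence is asserted by test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import AxisLine, DegenerateGeometryError, unit

__all__ = ["measure_ttg", "TTTGMatrix", "delta_table", "cohort_long", "cohort_delta"]


def measure_ttg(FMCP, FLCP, TGCP, TTP) -> float:
    """Signed TT-TG distance (mm) for right-canonical landmarks.

    The projection axis is ``unit(FLCP - FMCP)``; the result is independent of
    the magnitude of that vector and invariant under any common rigid motion
    of the four points.
    """
    FMCP = np.asarray(FMCP, dtype=float)
    FLCP = np.asarray(FLCP, dtype=float)
    if np.allclose(FMCP, FLCP):
        raise DegenerateGeometryError("FMCP and FLCP coincide; condylar axis undefined")
    a = AxisLine(FMCP, unit(FLCP - FMCP))
    rel = np.asarray(TTP, dtype=float) - np.asarray(TGCP, dtype=float)
    return float(rel @ a.direction)


@dataclass(frozen=True)
class TTTGMatrix:
    """Per-specimen TT-TG values over a pose grid.

    ``values`` maps ``(flexion_deg, rotation_deg)`` to TT-TG in mm; the
    baseline pose (0, 0) must be present and all values finite.
    """

    specimen_id: str
    values: dict[tuple[float, float], float]

    def __post_init__(self):
        normalised = {(float(f), float(r)): float(v) for (f, r), v in self.values.items()}
        object.__setattr__(self, "values", normalised)
        if (0.0, 0.0) not in normalised:
            raise ValueError(f"specimen {self.specimen_id}: baseline pose (0, 0) missing")
        if not all(np.isfinite(v) for v in normalised.values()):
            raise ValueError(f"specimen {self.specimen_id}: non-finite TT-TG value")

    @property
    def baseline(self) -> float:
        return self.values[(0.0, 0.0)]

    def to_series(self) -> pd.Series:
        idx = pd.MultiIndex.from_tuples(
            sorted(self.values), names=["flexion_deg", "rotation_deg"]
        )
        return pd.Series([self.values[k] for k in idx], index=idx, name="tttg_mm")


def delta_table(m: TTTGMatrix) -> pd.DataFrame:
    """Per-pose change relative to the unrotated tibia at the same flexion:
    ``delta(f, r) = tttg(f, r) - tttg(f, 0)`` for every r > 0 present.

    Raises if some flexion level with rotated poses lacks its unrotated cell.
    """
    s = m.to_series()
    rows = []
    for (f, r), v in s.items():
        if r == 0:
            continue
        if (f, 0.0) not in s.index:
            raise ValueError(
                f"specimen {m.specimen_id}: no unrotated cell at flexion {f}"
            )
        rows.append({"flexion_deg": f, "rotation_deg": r, "delta_tttg_mm": v - s[(f, 0.0)]})
    return pd.DataFrame(rows, columns=["flexion_deg", "rotation_deg", "delta_tttg_mm"])


def cohort_long(matrices) -> pd.DataFrame:
    """Stack per-specimen matrices into the long format
    ``specimen_id, flexion_deg, rotation_deg, tttg_mm``."""
    frames = []
    for m in matrices:
        df = m.to_series().reset_index()
        df.insert(0, "specimen_id", m.specimen_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def cohort_delta(long_df: pd.DataFrame) -> pd.DataFrame:
    """Long-format ΔTT-TG (vs the unrotated tibia at the same flexion) for a
    cohort table produced by :func:`cohort_long`."""
    base = long_df[long_df["rotation_deg"] == 0].set_index(["specimen_id", "flexion_deg"])[
        "tttg_mm"
    ]
    rot = long_df[long_df["rotation_deg"] > 0].copy()
    keys = list(zip(rot["specimen_id"], rot["flexion_deg"]))
    missing = [k for k in keys if k not in base.index]
    if missing:
        raise ValueError(f"missing unrotated cells for {sorted(set(missing))[:3]} ...")
    rot["delta_tttg_mm"] = rot["tttg_mm"].to_numpy() - base.loc[keys].to_numpy()
    return rot[["specimen_id", "flexion_deg", "rotation_deg", "delta_tttg_mm"]].reset_index(
        drop=True
    )
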