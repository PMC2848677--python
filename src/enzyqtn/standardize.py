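"""Plate-level standardization of raw enzyme-assay readings.

Raw microplate data arrive as one row per well with a maximal-rate reading
(V_max) and a blank reading (V_blank) taken on the same plate.  Net activity
is their difference.  Because plates are run in batches, net activities are
put on a common scale either by dividing by the mean net activity of the
plate's experimental wells ("plate_mean") or by the mean of the plate's
common reference wells ("reference_mean").  Blank wells never enter either
divisor.  Negative net activities are retained and flagged, never clamped,
since clamping would bias the plate means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SCHEMES = ("plate_mean", "reference_mean")
REQUIRED = ["line", "enzyme", "plate", "well", "role", "rep", "Vmax", "Vblank"]


def net_activity(v_max, v_blank):
    """Net activity = V_max - V_blank (kept as-is when negative)."""
    v_max = np.asarray(v_max, dtype=float)
    v_blank = np.asarray(v_blank, dtype=float)
    if not (np.all(np.isfinite(v_max)) and np.all(np.isfinite(v_blank))):
        raise ValueError("V_max and V_blank must be finite")
    out = v_max - v_blank
    return out if out.ndim else float(out)


def _check_table(measurements: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED if c not in measurements.columns]
    if missing:
        raise ValueError(f"measurement table lacks columns: {missing}")
    bad = measurements["Vblank"].isna() | measurements["Vmax"].isna()
    if bad.any():
        where = measurements.loc[bad, ["plate", "well"]].astype(str).agg(":".join, axis=1)
        raise ValueError(
            "missing V_max/V_blank at " + ", ".join(where.head(10)) + ("..." if bad.sum() > 10 else "")
        )
    return measurements


def standardize(measurements: pd.DataFrame, scheme: str = "reference_mean") -> pd.DataFrame:
    """Standardized (line x rep) by enzyme activity matrix.

    Each experimental well's net activity is divided by its plate's divisor:
    the mean net activity over experimental wells (``plate_mean``) or over
    reference wells (``reference_mean``).  Returns a DataFrame indexed by
    (line, rep) with one column per enzyme; ``.attrs['scheme']`` records the
    provenance and ``.attrs['negative_net']`` the count of flagged negative
    net activities.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}")
    df = _check_table(measurements).copy()
    df["net"] = net_activity(df["Vmax"].to_numpy(), df["Vblank"].to_numpy())

    role = "sample" if scheme == "plate_mean" else "ref"
    pool = df[df["role"] == role]
    if scheme == "reference_mean":
        plates = df.loc[df["role"] == "sample", ["enzyme", "plate"]].drop_duplicates()
        have = set(map(tuple, pool[["enzyme", "plate"]].drop_duplicates().to_numpy()))
        lacking = [p for p in map(tuple, plates.to_numpy()) if p not in have]
        if lacking:
            raise ValueError(f"plates without reference wells: {lacking}")
    divisor = pool.groupby(["enzyme", "plate"])["net"].mean()
    bad = divisor[divisor <= 0]
    if len(bad):
        raise ValueError(f"non-positive plate divisor for: {list(bad.index)}")

    samples = df[df["role"] == "sample"].copy()
    samples["std"] = samples["net"] / divisor.loc[
        pd.MultiIndex.from_frame(samples[["enzyme", "plate"]])
    ].to_numpy()
    matrix = samples.pivot_table(index=["line", "rep"], columns="enzyme", values="std")
    matrix.attrs["scheme"] = scheme
    matrix.attrs["negative_net"] = int((samples["net"] < 0).sum())
    return matrix


def zscore_by_enzyme(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each enzyme column (sample sd, n-1). Idempotent."""
    sd = matrix.std(ddof=1)
    constant = sd[(sd == 0) | sd.isna()]
    if len(constant):
        raise ValueError(f"constant enzyme column(s): {list(constant.index)}")
    out = (matrix - matrix.mean()) / sd
    out.attrs = dict(matrix.attrs)
    out.attrs["zscored"] = True
    return out


def line_means(matrix: pd.DataFrame) -> pd.DataFrame:
    """Mean over replicates per line; ``.attrs['n_obs']`` holds the counts."""
    if "line" in getattr(matrix.index, "names", []):
        grouped = matrix.groupby(level="line")
    else:
        grouped = matrix.groupby(level=0)
    out = grouped.mean()
    out.attrs["n_obs"] = grouped.count()
    return out
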