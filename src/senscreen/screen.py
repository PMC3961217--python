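"""Plate-wise Z-scores, replicate aggregation and control-anchored hit calls.

Each well's percent-marker-positive value is standardised against its own
plate (mean and sample SD of the plate's normalisation set, by default
the library wells only, so the strong control wells do not drag the
plate average). Replicate wells of a miRNA are aggregated by averaging
their Z-scores, and hits are called against the plate's own controls: an
up-hit must outscore the positive controls (BMI1 and JMJD3 knockdown,
which raise the senescence marker), a down-hit must underscore the p16
knockdown control. Fold changes are reported relative to the plate
average, the scale on which screen effect sizes are quoted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ZeroVariancePlateError",
    "plate_zscore",
    "score_wells",
    "summarize_controls",
    "aggregate_replicates",
    "fold_change_vs_plate",
    "call_hits",
]

UP_CONTROL_ROLES = ("BMI1i", "JMJD3i")
DOWN_CONTROL_ROLE = "p16i"


class ZeroVariancePlateError(ValueError):
    """Raised when a plate's normalisation set has no spread."""


def plate_zscore(values, norm_values, plate=None) -> np.ndarray:
    """Standardise well values against a plate's normalisation set.

    z_i = (x_i - mean(norm)) / sd(norm) with the sample SD (ddof=1).
    """
    x = np.asarray(values, dtype=float)
    norm = np.asarray(norm_values, dtype=float)
    norm = norm[np.isfinite(norm)]
    if norm.size < 2 or np.unique(norm).size < 2:
        raise ZeroVariancePlateError(
            f"plate {plate!r}: normalisation set needs >= 2 distinct values"
        )
    sd = norm.std(ddof=1)
    return (x - norm.mean()) / sd


def score_wells(
    wells: pd.DataFrame,
    platemap: pd.DataFrame,
    include_controls_in_norm: bool = False,
) -> pd.DataFrame:
    """Attach per-well Z-scores and plate averages to a well table.

    ``wells`` needs columns (plate, well, pct_positive); roles and sample
    ids are taken from the plate map. The normalisation set defaults to
    the plate's library wells; ``include_controls_in_norm`` switches to
    all wells. Induction-free technical controls (SCR_uninduced) are
    never part of the normalisation set.
    """
    df = wells.merge(
        platemap[["plate", "well", "sample", "role"]], on=["plate", "well"], how="left"
    )
    if df["role"].isna().any():
        missing = df.loc[df["role"].isna(), ["plate", "well"]].head()
        raise ValueError(f"wells absent from plate map, e.g.\n{missing}")
    out = []
    for plate, grp in df.groupby("plate", observed=True):
        if include_controls_in_norm:
            norm_mask = grp["role"] != "SCR_uninduced"
        else:
            norm_mask = grp["role"] == "library"
        norm = grp.loc[norm_mask & grp["pct_positive"].notna(), "pct_positive"]
        g = grp.copy()
        g["z"] = plate_zscore(g["pct_positive"], norm, plate=plate)
        g["plate_avg"] = norm.mean()
        out.append(g)
    return pd.concat(out, ignore_index=True)


def summarize_controls(scored: pd.DataFrame) -> pd.DataFrame:
    """Per-plate, per-control-role mean percent positive and mean Z."""
    ctl = scored[scored["role"] != "library"]
    return (
        ctl.groupby(["plate", "role"], observed=True)
        .agg(
            n_wells=("z", "size"),
            pct_positive=("pct_positive", "mean"),
            z=("z", "mean"),
        )
        .reset_index()
    )


def fold_change_vs_plate(sample_percents, plate_averages) -> float:
    """Fold change of a sample relative to the plate average.

    For multi-well samples this is the ratio of means, each well paired
    with its own plate's average.
    """
    p = np.asarray(sample_percents, dtype=float)
    a = np.asarray(plate_averages, dtype=float)
    if a.size != p.size:
        a = np.broadcast_to(a, p.shape)
    if np.any(a <= 0):
        raise ValueError("plate average must be > 0 to form a fold change")
    return float(p.mean() / a.mean())


def aggregate_replicates(scored: pd.DataFrame) -> pd.DataFrame:
    """Collapse scored library wells to one row per miRNA.

    Sample Z = mean of well Zs; sample percent = mean of well percents;
    fold change = ratio of the sample mean to the mean of the
    contributing plates' averages.
    """
    lib = scored[scored["role"] == "library"]
    rows = []
    for sample, grp in lib.groupby("sample", observed=True):
        rows.append(
            {
                "sample": sample,
                "n_wells": len(grp),
                "pct_positive": float(grp["pct_positive"].mean()),
                "z": float(grp["z"].mean()),
                "fold_change": fold_change_vs_plate(
                    grp["pct_positive"].to_numpy(), grp["plate_avg"].to_numpy()
                ),
                "plates": tuple(sorted(grp["plate"].unique())),
            }
        )
    return pd.DataFrame(rows)


def call_hits(
    samples: pd.DataFrame,
    control_summary: pd.DataFrame,
    mode: str = "per-plate",
) -> pd.DataFrame:
    """Control-anchored hit calls.

    up-hit  <=> sample Z strictly greater than every positive-control Z
    (BMI1i, JMJD3i) of the plates the sample ran on; down-hit <=> sample
    Z strictly below the p16i control Z. ``mode='pooled'`` anchors on the
    screen-wide mean control Zs instead of per-plate values. Ties are
    never hits.
    """
    if mode not in ("per-plate", "pooled"):
        raise ValueError("mode must be 'per-plate' or 'pooled'")
    roles_present = set(control_summary["role"])
    required = set(UP_CONTROL_ROLES) | {DOWN_CONTROL_ROLE}
    if not required <= roles_present:
        raise ValueError(f"missing control roles: {sorted(required - roles_present)}")

    if mode == "pooled":
        pooled = control_summary.groupby("role", observed=True)["z"].mean()
        up_thr_global = float(pooled[list(UP_CONTROL_ROLES)].max())
        down_thr_global = float(pooled[DOWN_CONTROL_ROLE])
    else:
        per_plate = control_summary.pivot(index="plate", columns="role", values="z")
        missing = per_plate[list(required)].isna()
        if missing.to_numpy().any():
            bad = per_plate.index[missing.any(axis=1)].tolist()
            raise ValueError(f"plates missing control roles: {bad}")

    out = samples.copy()
    up_thr = np.empty(len(out))
    down_thr = np.empty(len(out))
    for i, row in enumerate(out.itertuples(index=False)):
        if mode == "pooled":
            up_thr[i] = up_thr_global
            down_thr[i] = down_thr_global
        else:
            plates = list(row.plates)
            up_thr[i] = per_plate.loc[plates, list(UP_CONTROL_ROLES)].to_numpy().max()
            down_thr[i] = per_plate.loc[plates, DOWN_CONTROL_ROLE].to_numpy().min()
    out["up_threshold"] = up_thr
    out["down_threshold"] = down_thr
    out["hit"] = np.select(
        [out["z"] > out["up_threshold"], out["z"] < out["down_threshold"]],
        ["up", "down"],
        default="none",
    )
    return out
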