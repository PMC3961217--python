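"""End-to-end screen simulation + analysis runs.

Ties the generator to the analysis stages: build a plate map with ground
truth, simulate every well's cells, calibrate the positivity threshold on
the uninduced scrambled controls, quantify per image and per well, score
plate-wise Z-scores, and call control-anchored hits. Used by the
simulation studies (hit recovery, null calibration) and the acceptance
checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import imaging, screen
from .simulate import SimulationConfig, SimulationTruth, make_plate_maps, simulate_screen_cells

__all__ = ["ScreenRun", "run_screen", "evaluate_recovery"]


@dataclass
class ScreenRun:
    config: SimulationConfig
    platemap: pd.DataFrame
    truth: SimulationTruth
    marker_threshold: float
    wells: pd.DataFrame  # per-well quantification, scored (z, plate_avg)
    controls: pd.DataFrame  # per-plate per-role summary
    results: pd.DataFrame  # per-miRNA ScreenResult rows with hit calls


def run_screen(
    config: SimulationConfig,
    seed: int | None = None,
    hit_mode: str = "per-plate",
) -> ScreenRun:
    """Simulate a full screen and analyse it.

    ``seed`` overrides ``config.rng_seed`` when given. Cells are carried
    as intensity tables (no image rendering); the marker-positivity
    threshold is calibrated from the pooled uninduced scrambled-control
    cells at the default k = 3.
    """
    if seed is not None:
        config = config.replace(rng_seed=int(seed))
    config.validate()
    platemap, truth = make_plate_maps(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))
    cells = simulate_screen_cells(platemap, truth, config, rng)

    uninduced = cells.loc[cells["role"] == "SCR_uninduced", "marker_intensity"]
    threshold = imaging.calibrate_threshold(uninduced)

    per_image = imaging.quantify_cell_table(cells, threshold)
    wells = imaging.summarize_wells(per_image)
    scored = screen.score_wells(wells, platemap)
    controls = screen.summarize_controls(scored)
    samples = screen.aggregate_replicates(scored)
    results = screen.call_hits(samples, controls, mode=hit_mode)
    results = results.merge(truth.mirna_effects, on="sample", how="left")
    return ScreenRun(
        config=config,
        platemap=platemap,
        truth=truth,
        marker_threshold=threshold,
        wells=scored,
        controls=controls,
        results=results,
    )


def evaluate_recovery(results: pd.DataFrame) -> dict[str, float]:
    """Recovery and false-call rates of a screen run against its truth.

    A planted hit counts as recovered when it is called a hit in the
    planted direction; a false call is any non-"none" call on a null
    miRNA.
    """
    planted = results[results["direction"] != "none"]
    nulls = results[results["direction"] == "none"]
    recovered = (planted["hit"] == planted["direction"]).sum()
    false_calls = (nulls["hit"] != "none").sum()
    return {
        "n_planted": int(len(planted)),
        "n_recovered": int(recovered),
        "recovery_rate": float(recovered / len(planted)) if len(planted) else float("nan"),
        "n_null": int(len(nulls)),
        "n_false_calls": int(false_calls),
        "false_call_rate": float(false_calls / len(nulls)) if len(nulls) else float("nan"),
    }
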