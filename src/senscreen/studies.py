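"""Reusable simulation studies over the full pipeline.

Each study builds its inputs with the generators in :mod:`senscreen.simulate`,
runs the relevant analysis stages, and returns the measured quantities
together with the planted truth, so calibration and recovery claims can be
checked end to end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import imaging
from .expression import call_de, split_de
from .pipeline import evaluate_recovery, run_screen
from .seeds import MatureMiRNA, extract_seed, genes_with_sites, overlap_with_de
from .simulate import (
    SimulationConfig,
    render_well_images,
    simulate_expression,
    simulate_utrs,
    simulate_well,
)

__all__ = [
    "hit_recovery_study",
    "null_screen_study",
    "segmentation_fidelity_study",
    "de_overlap_study",
]


def hit_recovery_study(seed: int = 0, config: SimulationConfig | None = None) -> dict:
    """Full-scale screen with planted hits; recovery and effect-size stats."""
    cfg = config or SimulationConfig()
    run = run_screen(cfg, seed=seed)
    stats_ = evaluate_recovery(run.results)
    res = run.results
    up = res[(res["direction"] == "up") & (res["hit"] == "up")]
    down = res[(res["direction"] == "down") & (res["hit"] == "down")]
    stats_.update(
        {
            "n_up_called": int((res["hit"] == "up").sum()),
            "n_down_called": int((res["hit"] == "down").sum()),
            "up_hit_mean_fold": float(up["fold_change"].mean()) if len(up) else float("nan"),
            "down_hit_mean_fold_reduction": float((1.0 / down["fold_change"]).mean())
            if len(down)
            else float("nan"),
        }
    )
    return stats_


def null_screen_study(
    n_screens: int = 10, base_seed: int = 0, config: SimulationConfig | None = None
) -> dict:
    """Screens with every library effect at 1.0: Z calibration + hit rate.

    Per screen: a KS test of the sample Z-scores against a normal with
    fitted location/scale, the empirical hit rate, and the hit rate
    expected from normal theory given the realised control-anchored
    thresholds (the control-quantile expectation).
    """
    cfg = (config or SimulationConfig()).replace(hit_fraction=0.0)
    ks_ps, emp_rates, exp_rates = [], [], []
    for i in range(n_screens):
        run = run_screen(cfg, seed=base_seed + i)
        z = run.results["z"].to_numpy()
        loc, scale = z.mean(), z.std(ddof=1)
        ks_ps.append(float(stats.kstest(z, "norm", args=(loc, scale)).pvalue))
        emp_rates.append(float((run.results["hit"] != "none").mean()))
        expected = (
            stats.norm.sf(run.results["up_threshold"] / scale)
            + stats.norm.cdf(run.results["down_threshold"] / scale)
        )
        exp_rates.append(float(expected.mean()))
    n_total = n_screens * cfg.n_library_mirnas
    return {
        "ks_pvalues": ks_ps,
        "min_ks_p": float(min(ks_ps)),
        "empirical_hit_rate": float(np.mean(emp_rates)),
        "expected_hit_rate": float(np.mean(exp_rates)),
        "n_samples_total": n_total,
    }


def segmentation_fidelity_study(
    n_wells: int = 50, seed: int = 0, config: SimulationConfig | None = None
) -> pd.DataFrame:
    """Render wells, segment them back, and compare against the cell tables.

    Wells carry a mix of null, up (x2.25) and down (/7) effects. The
    marker-positivity threshold is calibrated separately in table space
    and in measured-image space from rendered uninduced control wells.
    Returns one row per well: planted and segmented cell counts, and the
    well percent-positive by the table and image routes.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    effects = ([1.0] * (n_wells - n_wells // 5 * 2)
               + [cfg.up_hit_fold] * (n_wells // 5)
               + [1.0 / 7.0] * (n_wells // 5))

    # calibration wells (uninduced scrambled controls), both spaces
    tab_ctl, img_ctl = [], []
    for _ in range(8):
        ctl = simulate_well(1.0, cfg, rng, role="SCR_uninduced", with_positions=True)
        tab_ctl.append(ctl["marker_intensity"])
        for nuc, mark in render_well_images(ctl, rng=rng):
            _, found = imaging.segment_nuclei(nuc, mark)
            img_ctl.append(found["marker_intensity"])
    thr_tab = imaging.calibrate_threshold(pd.concat(tab_ctl))
    thr_img = imaging.calibrate_threshold(pd.concat(img_ctl))

    rows = []
    for w, effect in enumerate(effects):
        cells = simulate_well(effect, cfg, rng, with_positions=True)
        # table route
        tab_pcts, img_pcts, n_found = [], [], 0
        for f, (nuc, mark) in enumerate(render_well_images(cells, rng=rng)):
            sub = cells[cells["field"] == f]
            _, tab_pct = imaging.classify_positive(sub, thr_tab)
            tab_pcts.append(tab_pct)
            _, found = imaging.segment_nuclei(nuc, mark)
            n_found += len(found)
            _, img_pct = imaging.classify_positive(found, thr_img)
            img_pcts.append(img_pct)
        rows.append(
            {
                "well": w,
                "effect": effect,
                "n_planted": len(cells),
                "n_segmented": n_found,
                "pct_table": imaging.quantify_well(tab_pcts)["pct_positive"],
                "pct_image": imaging.quantify_well(img_pcts)["pct_positive"],
            }
        )
    df = pd.DataFrame(rows)
    df["count_error_pct"] = 100.0 * (df["n_segmented"] - df["n_planted"]) / df["n_planted"]
    df["pct_abs_diff"] = (df["pct_image"] - df["pct_table"]).abs()
    return df


def de_overlap_study(seed: int = 0) -> dict:
    """Round trip: planted seed sites + planted down-regulation -> overlap.

    200 genes; 40 carry a seed site in their UTR. Of those, 19 are planted
    2-fold down and 21 are planted 2-fold up; 11 non-seed genes are also
    planted down. At low biological dispersion every planted effect is
    recovered, so the DE-down / seed-target intersection must be exactly
    the 19 planted genes.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 6]))
    mirna = MatureMiRNA("miR-378a-5p-like", "CUCCUGACUCCAGGUCCUGUGU")
    n_genes = 200
    genes = [f"gene{i + 1:04d}" for i in range(n_genes)]
    target_idx = list(range(40))
    down_target = genes[:19]
    up_target = genes[19:40]
    down_other = genes[40:51]

    site_types = ["8mer", "7mer-m8", "7mer-A1", "6mer"]
    planted_sites = [
        (i, 60 + (i % 10) * 13, site_types[i % 4]) for i in target_idx
    ]
    utrs, utr_truth = simulate_utrs(
        n_genes, 500, planted_sites, extract_seed(mirna), rng,
        transcript_prefix="tx",
    )
    tx2gene = {f"tx{i + 1:04d}": genes[i] for i in range(n_genes)}

    fc = {g: 0.5 for g in down_target}
    fc.update({g: 2.0 for g in up_target})
    fc.update({g: 0.5 for g in down_other})
    expr, groups, expr_truth = simulate_expression(
        n_genes, fc, n_per_group=3, dispersion=0.05, rng=rng
    )

    targets = genes_with_sites(utrs, mirna, tx2gene)
    de = call_de(expr, groups, q_threshold=0.05)
    up_de, down_de = split_de(de)
    report = overlap_with_de(targets, up_de["gene"], down_de["gene"])
    return {
        "report": report,
        "targets": targets,
        "planted_target_genes": set(genes[i] for i in target_idx),
        "planted_down_target_genes": set(down_target),
        "planted_up_target_genes": set(up_target),
        "utr_truth": utr_truth,
        "expr_truth": expr_truth,
        "de": de,
    }
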