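"""Recovery and concordance experiments over the pipeline's own generators.

Each function rebuilds its inputs from scratch (synthetic slides, simulated
cohorts, or the reference-cohort margins), runs the relevant pipeline stage
and measures how well the known truth is recovered. Used by the acceptance
checks and reusable for sensitivity analyses.
"""

from __future__ import annotations

import warnings

import numpy as np

from hypoxvasc import if_quant, mvd as mvd_mod, survival
from hypoxvasc.cohort import cell_percentage, counts_table
from hypoxvasc.images import BinaryImage, RegionMask
from hypoxvasc.mvd import HotspotField, count_in_frame, find_hotspots, label_vessels
from hypoxvasc.synthetic_cohort import CohortSimParams, generate_cohort, reference_cohort
from hypoxvasc.synthetic_slides import SlideSimParams, generate_slide

FCAIX_PANEL_FRACTIONS = (0.0, 0.005, 0.01, 0.05, 0.12, 0.3)


def table1_metrics() -> dict[str, float]:
    """Descriptive percentages of the reconstructed reference cohort."""
    df = reference_cohort()
    return {
        "caix_mvd_high_prevalence_pct": cell_percentage(df, "group", "caix_mvd_high"),
        "recurrence_pct_caix_mvd_high": cell_percentage(
            df, "recurrence", "yes", col_level="caix_mvd_high"
        ),
        "recurrence_pct_rest": cell_percentage(df, "recurrence", "yes", col_level="rest"),
        "distant_recurrence_pct_caix_mvd_high": cell_percentage(
            df, "recurrence_distant", "yes", col_level="caix_mvd_high"
        ),
        "distant_recurrence_pct_rest": cell_percentage(
            df, "recurrence_distant", "yes", col_level="rest"
        ),
        "ec_mortality_pct_caix_mvd_high": cell_percentage(
            df, "death_ec_related", "yes", col_level="caix_mvd_high"
        ),
        "ec_mortality_pct_rest": cell_percentage(
            df, "death_ec_related", "yes", col_level="rest"
        ),
        "overall_recurrence_pct": cell_percentage(df, "recurrence", "yes"),
        "caix_positive_pct": cell_percentage(df, "caix_positive", "yes"),
        "overall_distant_recurrence_pct": cell_percentage(df, "recurrence_distant", "yes"),
    }


def recurrence_chisquare_p() -> float:
    """Uncorrected chi-square p on the recurrence-by-group cells."""
    table = counts_table(reference_cohort(), "recurrence", "group").to_numpy()
    return survival.compare_categorical(table).p_value


def fcaix_recovery_panel(seed: int = 0, n_slides: int = 20) -> dict:
    """Quantify synthetic slides spanning the panel of true fractions.

    Thresholds use the background-region statistic (mean + 3 SD over the
    non-tumour area), the reproducible surrogate for per-sample
    above-background thresholding.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_slides)
    errors, class_ok, truths, measured = [], [], [], []
    for i in range(n_slides):
        frac = FCAIX_PANEL_FRACTIONS[i % len(FCAIX_PANEL_FRACTIONS)]
        params = SlideSimParams(
            image_shape=(384, 384),
            true_caix_fraction=frac,
            n_vessels=10,
            seed=int(seeds[i] % (2**31)),
        )
        _, caix, _, truth = generate_slide(params)
        bg_mask = RegionMask(~truth.tumour_mask.include)
        res = if_quant.quantify_caix(
            caix, truth.tumour_mask, threshold_method="background", background_mask=bg_mask
        )
        errors.append(abs(res.fcaix - truth.true_caix_fraction))
        truths.append(truth.true_caix_fraction)
        measured.append(res.fcaix)
        if abs(truth.true_caix_fraction - 0.01) >= 0.005:
            class_ok.append(res.caix_positive == (truth.true_caix_fraction > 0.01))
    return {
        "max_abs_error": float(max(errors)),
        "mean_abs_error": float(np.mean(errors)),
        "classification_accuracy": float(np.mean(class_ok)),
        "n_slides": n_slides,
        "errors": errors,
        "truths": truths,
        "measured": measured,
    }


def _random_vessel_map(rng: np.random.Generator, shape=(64, 64), density=0.06):
    return rng.uniform(size=shape) < density


def counting_frame_agreement(seed: int = 0, n_maps: int = 100) -> dict:
    """Frame-rule vs brute-force per-pixel edge classification, plus tiling.

    Returns the fraction of (map, field) instances where the fast counter
    agrees with the brute-force classifier, and the fraction of generator
    slides on which tiling the frame over the image counts every vessel
    exactly once.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    total = 0
    for _ in range(n_maps):
        grid = _random_vessel_map(rng)
        objs = label_vessels(BinaryImage(grid, 0, "vessel"), min_pixels=0)
        origin = (int(rng.integers(0, 40)), int(rng.integers(0, 40)))
        size = (int(rng.integers(8, 24)), int(rng.integers(8, 24)))
        n, counted, excluded = count_in_frame(objs, HotspotField(origin, size, 0))
        ok = True
        r0, c0 = origin
        r1, c1 = r0 + size[0] - 1, c0 + size[1] - 1
        for obj in objs:
            max_r, max_c = int(obj.rows.max()), int(obj.cols.max())
            inter = (
                (obj.rows >= r0) & (obj.rows <= r1) & (obj.cols >= c0) & (obj.cols <= c1)
            ).any()
            crosses = max_r > r1 or max_c > c1
            if r0 <= max_r <= r1 and c0 <= max_c <= c1:
                expected = "counted"
            elif inter and crosses:
                expected = "excluded"
            else:
                expected = "outside"
            got = (
                "counted"
                if obj.id in counted
                else ("excluded" if obj.id in excluded else "outside")
            )
            ok &= got == expected
        agree += ok
        total += 1

    tiling_ok = 0
    n_tiling = 10
    for i in range(n_tiling):
        params = SlideSimParams(
            image_shape=(192, 192),
            tumour_mask_fraction=1.0,
            true_caix_fraction=0.0,
            n_vessels=25,
            noise_speckle_rate=0.0,
            noise_sigma=0.0,
            seed=seed + 1000 + i,
        )
        _, _, _, truth = generate_slide(params)
        objs = list(truth.vessel_objects)
        counted_total = 0
        for r0 in range(0, 192, 48):
            for c0 in range(0, 192, 48):
                counted_total += count_in_frame(
                    objs, HotspotField((r0, c0), (48, 48), 0)
                )[0]
        tiling_ok += counted_total == len(objs)
    return {
        "edge_rule_agreement": agree / total,
        "tiling_exact_once": tiling_ok / n_tiling,
        "n_maps": n_maps,
    }


def hotspot_optimality(seed: int = 0, n_maps: int = 50) -> dict:
    """Greedy first field vs exhaustive maximum at stride 1 on random maps."""
    rng = np.random.default_rng(seed)
    matches = 0
    for _ in range(n_maps):
        grid = _random_vessel_map(rng, shape=(40, 40), density=0.05)
        objs = label_vessels(BinaryImage(grid, 0, "vessel"), min_pixels=0)
        fsize = (12, 12)
        best = find_hotspots(objs, grid.shape, fsize, k=1, stride=1)[0]
        exhaustive = max(
            count_in_frame(objs, HotspotField((r, c), fsize, 0))[0]
            for r in range(grid.shape[0] - fsize[0] + 1)
            for c in range(grid.shape[1] - fsize[1] + 1)
        )
        matches += best.vessel_count == exhaustive
    return {"fraction_matching_exhaustive": matches / n_maps, "n_maps": n_maps}


def cox_recovery(
    seed: int = 0,
    n_patients: int = 5000,
    n_replicates: int = 200,
    true_hr: float = 2.0,
) -> dict:
    """Bias of the estimated log-HR and Wald 95% CI coverage."""
    log_hrs = []
    covered = 0
    true_log = float(np.log(true_hr))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_replicates):
            params = CohortSimParams(
                n_patients=n_patients,
                log_hazard_ratios={"biomarker_group": true_log},
                seed=(seed * 100003 + i) % (2**31),
            )
            df = generate_cohort(params)
            res = survival.cox_fit(df, "raw", ["biomarker_group"])
            log_hrs.append(np.log(res.hr["biomarker_group"]))
            lo, hi = res.ci95["biomarker_group"]
            covered += lo <= true_hr <= hi
    log_hrs = np.asarray(log_hrs)
    return {
        "true_hr": true_hr,
        "mean_hr": float(np.exp(log_hrs.mean())),
        "loghr_bias": float(log_hrs.mean() - true_log),
        "ci95_coverage": covered / n_replicates,
        "n_patients": n_patients,
        "n_replicates": n_replicates,
    }


def logrank_null_rejection_rate(
    seed: int = 0, n_patients: int = 300, n_replicates: int = 400
) -> dict:
    """Type-I error of the two-group log-rank test under the null."""
    rejections = 0
    done = 0
    for i in range(n_replicates):
        params = CohortSimParams(
            n_patients=n_patients,
            log_hazard_ratios={"mvd_high": 0.0},
            seed=(seed * 99991 + i) % (2**31),
        )
        df = generate_cohort(params)
        try:
            res = survival.logrank_test(
                df["event_time"], df["event_observed"], df["mvd_high"]
            )
        except ValueError:
            continue
        rejections += res.p_value < 0.05
        done += 1
    return {
        "rejection_rate": rejections / done,
        "n_replicates": done,
        "n_patients": n_patients,
    }
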