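"""End-to-end analysis binding all stages into one reproducible run.

``run_full_analysis`` executes the four stages of the aggregation study
— quadrat dispersion over the survey campaign, per-tank/per-frame MAD
randomness tests, Y-tube assay comparisons, and the saponin differential
— and emits a report directory containing one CSV table per stage plus a
machine-readable ``report.json``.  Inputs default to the synthetic study
bundle generated from the configured seed, so a full run works out of
the box; callers may pass their own loaded data instead.

Outputs are written atomically: everything is staged in a temporary
sibling directory and moved into place only on success, so a failed run
never leaves partial outputs.
"""

from __future__ import annotations

import json
import logging
import os
import shutil
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import assays as ba
from . import quadrats as qd
from . import saponins as sp
from . import synthetic as syn
from .io import RunConfig
from .patterns import mad_test

log = logging.getLogger(__name__)

ANOVA_RESPONSES = ("ratio", "t_stat", "significant")


def _anova_response_matrix(surveys, alpha, which: str) -> pd.DataFrame:
    """Pens x months matrix of the chosen per-survey aggregation measure."""
    if which not in ANOVA_RESPONSES:
        raise ValueError(f"anova response must be one of {ANOVA_RESPONSES}")
    cells = {}
    for sv in surveys:
        try:
            res = qd.dispersion_test(sv.layer("combined"), alpha=alpha)
        except ValueError:
            continue  # excluded survey; completeness is checked below
        value = {
            "ratio": res.ratio,
            "t_stat": res.t_stat,
            "significant": float(res.significant),
        }[which]
        cells[(sv.pen_id, sv.month)] = value
    df = pd.Series(cells).unstack()
    if df.isna().any().any():
        raise ValueError(
            "survey campaign is incomplete (empty or excluded pen-month cells); "
            "the no-replication ANOVA needs a complete matrix"
        )
    return df


def default_assay_records(seed) -> tuple[list, object]:
    """Synthetic Y-tube records at the study's stimulus panel scale.

    Movement probabilities follow the observed range: strong attractants
    around 0.65-0.85, non-attractants near the control baseline of 0.2;
    about 20-55 trials per stimulus.
    """
    panel = [
        ("juvenile-conditioned water", 0.67, 55),
        ("adult-conditioned water", 0.33, 33),
        ("H. leucospilota adult", 0.80, 20),
        ("adult viscera saponin extract", 0.75, 20),
        ("juvenile conditioned-water saponin extract", 0.70, 20),
        ("boiled juvenile-conditioned water", 0.85, 20),
        ("sediment (food)", 0.90, 20),
        ("starved juvenile-conditioned water", 0.25, 20),
        ("fecal matter", 0.20, 20),
    ]
    seeds = syn._spawn(seed, len(panel) + 1)
    records = [
        syn.gen_assay_outcomes(p, n, s, stimulus=label)
        for (label, p, n), s in zip(panel, seeds[:-1])
    ]
    control = syn.gen_assay_outcomes(0.2, 40, seeds[-1], stimulus="control")
    return records, control


def run_full_analysis(
    config: RunConfig,
    surveys=None,
    tanks=None,
    assay_records=None,
    control=None,
    profiles=None,
) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Returns the report dictionary.  Any argument left as None is filled
    with the synthetic bundle for the configured seed; ``tanks`` is a
    list of (label, PointPattern) pairs.
    """
    root = np.random.SeedSequence(config.seed).spawn(5)
    report: dict = {"config": config.to_dict(), "seed": config.seed}

    if surveys is None:
        surveys = syn.gen_survey_campaign(clustered=config.clustered, seed=root[0])
    if tanks is None:
        patterns = syn.gen_aquarium_experiments(
            clustered=config.clustered, seed=root[1]
        )
        tanks = [(f"tank_{i + 1:02d}", p) for i, p in enumerate(patterns)]
    if assay_records is None or control is None:
        assay_records, control = default_assay_records(root[2])
    if profiles is None:
        profiles = sp.load_reference_profiles()

    # --- quadrat stage ----------------------------------------------------
    batch = qd.batch_table(surveys, alpha=config.alpha_dispersion)
    mean_q, mean_m2, occupancy, max_count = qd.density_summary(surveys)
    rows, excluded = [], []
    for sv in surveys:
        try:
            r = qd.dispersion_test(sv.layer("combined"), config.alpha_dispersion)
        except ValueError as exc:
            log.warning("survey %s %s excluded: %s", sv.pen_id, sv.month, exc)
            excluded.append({"pen_id": sv.pen_id, "month": sv.month, "reason": str(exc)})
            continue
        rows.append(
            {
                "pen_id": sv.pen_id,
                "month": sv.month,
                "n": r.n,
                "mean": r.mean,
                "variance": r.variance,
                "ratio": r.ratio,
                "t_stat": r.t_stat,
                "p_value": r.p_value,
                "significant": r.significant,
            }
        )
    per_survey = pd.DataFrame(rows)
    response = config.extra.get("anova_response", "ratio")
    try:
        matrix = _anova_response_matrix(surveys, config.alpha_dispersion, response)
        anova = qd.anova_two_way_no_rep(matrix.to_numpy())
        anova_report = {
            "response": response,
            "f_pen": anova.f_row, "p_pen": anova.p_row, "df_pen": anova.df_row,
            "f_month": anova.f_col, "p_month": anova.p_col, "df_month": anova.df_col,
            "n_pens": matrix.shape[0], "n_months": matrix.shape[1],
        }
    except ValueError as exc:
        log.warning("two-way ANOVA skipped: %s", exc)
        anova_report = {"response": response, "skipped": str(exc)}
    surf = [sv.layer("surface").mean() for sv in surveys]
    bur = [sv.layer("buried").mean() for sv in surveys]
    by_pen = pd.DataFrame({"pen": [sv.pen_id for sv in surveys], "s": surf, "b": bur})
    pen_means = by_pen.groupby("pen").mean()
    t_pair, df_pair, p_pair = qd.paired_t(
        pen_means["s"].to_numpy(), pen_means["b"].to_numpy()
    )
    report["quadrats"] = {
        "alpha": config.alpha_dispersion,
        "n_surveys": len(surveys),
        "density": {
            "mean_per_quadrat": mean_q,
            "mean_per_m2": mean_m2,
            "occupancy_fraction": occupancy,
            "max_count": max_count,
        },
        "batch": batch.to_dict(orient="records"),
        "excluded_surveys": excluded,
        "anova": anova_report,
        "paired_t_surface_vs_buried": {
            "t": t_pair, "df": df_pair, "p_two_sided": p_pair, "n": len(pen_means)
        },
    }

    # --- tank stage -------------------------------------------------------
    tank_seeds = np.random.SeedSequence((config.seed, 1)).spawn(len(tanks))
    tank_rows = []
    for (label, pattern), s in zip(tanks, tank_seeds):
        res = mad_test(pattern, n_sim=config.n_sim, seed=s)
        tank_rows.append(
            {
                "tank": label,
                "n": pattern.n,
                "observed_stat": res.observed_stat,
                "n_sim": res.n_sim,
                "p_value": res.p_value,
                "significant": res.p_value < config.alpha_pattern,
            }
        )
        log.info(
            "tank %s: n=%d T=%.3f p=%.4f", label, pattern.n,
            res.observed_stat, res.p_value,
        )
    tank_df = pd.DataFrame(tank_rows)
    report["tanks"] = {
        "alpha": config.alpha_pattern,
        "n_sim": config.n_sim,
        "n_tanks": len(tank_rows),
        "n_significant": int(tank_df["significant"].sum()),
        "tests": tank_rows,
    }

    # --- assay stage ------------------------------------------------------
    assay_rows = []
    for rec in assay_records:
        res = ba.assay_vs_control(rec, control, alpha=config.alpha_assay)
        assay_rows.append(
            {
                "stimulus": rec.stimulus,
                "n": rec.total,
                "pct_moved": round(res.percent_moved),
                "control_n": control.total,
                "control_pct_moved": round(100.0 * control.moved / control.total),
                "p_value": res.p_value,
                "significant": res.significant,
            }
        )
    report["assays"] = {
        "alpha": config.alpha_assay,
        "control": {"label": control.stimulus, "moved": control.moved, "n": control.total},
        "tests": assay_rows,
    }

    # --- saponin stage ----------------------------------------------------
    matrix_df = sp.profile_matrix(profiles)
    unique_all = sp.attractive_unique(profiles, rule="all-attractive")
    unique_any = sp.attractive_unique(profiles, rule="any-attractive")
    report["saponins"] = {
        "n_entries": len(profiles.library),
        "n_samples": len(profiles.samples),
        "attractive_unique_all": [e.mz_na for e in unique_all],
        "attractive_unique_any": [e.mz_na for e in unique_any],
        "diversity": sp.diversity_summary(profiles).reset_index().to_dict(orient="records"),
    }

    # --- atomic write -----------------------------------------------------
    out_dir = Path(config.out_dir)
    out_dir.parent.mkdir(parents=True, exist_ok=True)
    staging = Path(tempfile.mkdtemp(prefix=".staging-", dir=out_dir.parent))
    try:
        per_survey.to_csv(staging / "quadrat_tests.csv", index=False)
        batch.to_csv(staging / "quadrat_batch_summary.csv", index=False)
        tank_df.to_csv(staging / "tank_tests.csv", index=False)
        pd.DataFrame(assay_rows).to_csv(staging / "assay_tests.csv", index=False)
        matrix_df.to_csv(staging / "saponin_matrix.csv")
        with open(staging / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonify)
        if out_dir.exists():
            shutil.rmtree(out_dir)
        os.replace(staging, out_dir)
    except BaseException:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    return report


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
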