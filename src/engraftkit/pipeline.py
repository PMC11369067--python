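"""End-to-end orchestration: profiles + metadata -> engraftment score table.

Ties the modules together in the order an analyst would run them: normalize
and threshold the abundance table, derive each donor's core species, build
each recipient's donor-derived species set, compute the per-window metric
triplets, and normalize them into total engraftment scores.  Also provides
the cohort comparisons (rank-sum by group, two-way ANOVA with arm and donor
as factors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohort_stats, donor_core, engraftment, profiles_io
from .engraftment import ClrConfig, EngraftmentResult, ScoreNormalization
from .profiles_io import FIRST_POST_FMT_WEEK, AnalysisConfig


@dataclass
class CohortScores:
    """Engraftment scores plus the intermediates needed to audit them."""

    scores: pd.DataFrame  # one row per subject x window
    normalizations: dict[str, ScoreNormalization]
    core_sets: dict[str, donor_core.CoreSpeciesSet]
    donor_derived: dict[str, donor_core.DonorDerivedSet]
    retained_fraction: pd.Series = field(default_factory=pd.Series)


def score_cohort(
    profiles: pd.DataFrame,
    metadata: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
    clr_cfg: ClrConfig | None = None,
    first_post_fmt_week: int = FIRST_POST_FMT_WEEK,
) -> CohortScores:
    """Run the full engraftment pipeline on a profiled cohort.

    Subjects contribute to every window where they have samples; a subject
    with an empty donor-derived set gets SEI and similarity but a missing
    (NaN) SEF and is excluded from SEF-based normalization.
    """
    cfg = cfg or AnalysisConfig()
    clr_cfg = clr_cfg or ClrConfig(tau=cfg.tau)
    profiles_io.validate_cohort(profiles, metadata, first_post_fmt_week)
    relative = profiles_io.to_relative(profiles)
    table = profiles_io.apply_detection_threshold(relative, cfg.threshold)
    retained = profiles_io.retained_fraction(table)

    donors = metadata[metadata["role"] == "donor"]
    recipients = metadata[metadata["role"] == "recipient"]
    core_sets = {
        donor_id: donor_core.donor_core_species(
            table.loc[rows.index], tau=cfg.tau, min_samples=cfg.min_core_samples, donor_id=str(donor_id)
        )
        for donor_id, rows in donors.groupby("donor_id")
    }

    results: list[EngraftmentResult] = []
    derived: dict[str, donor_core.DonorDerivedSet] = {}
    for subject, rows in recipients.groupby("subject_id"):
        subject = str(subject)
        donor_id = str(rows["donor_id"].iloc[0])
        donor_table = table.loc[donors.index[donors["donor_id"] == donor_id]]
        pre_rows = rows[rows["week"] < first_post_fmt_week]
        dd = donor_core.donor_derived_species(core_sets[donor_id], table.loc[pre_rows.index], cfg.tau, subject)
        derived[subject] = dd
        baseline_sample = table.loc[pre_rows.sort_values("week").index[-1]]
        for window in cfg.windows:
            in_window = rows[[window.contains(int(w)) for w in rows["week"]]]
            if len(in_window) == 0:
                continue  # dropouts: no imputation, subject skips the window
            window_table = table.loc[in_window.index]
            sei = engraftment.sei_window(window_table, dd, cfg.tau)
            sef = engraftment.sef_window(window_table, dd, cfg.tau) if dd.species else float("nan")
            similarity = engraftment.donor_similarity(window_table, baseline_sample, donor_table, clr_cfg)
            results.append(
                EngraftmentResult(
                    subject_id=subject,
                    window=window.name,
                    sei=sei,
                    sef=sef,
                    similarity=similarity,
                    n_samples_in_window=len(in_window),
                )
            )

    results, norms = engraftment.total_engraftment_scores(results)
    scores = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "window": r.window,
                "sei": r.sei,
                "sef": r.sef,
                "similarity": r.similarity,
                "total_score": r.total_score,
                "n_samples": r.n_samples_in_window,
            }
            for r in results
        ]
    )
    return CohortScores(
        scores=scores,
        normalizations=norms,
        core_sets=core_sets,
        donor_derived=derived,
        retained_fraction=retained,
    )


def compare_by_group(
    scores: pd.DataFrame,
    group_of_subject: pd.Series,
    test: str = "wilcoxon",
    metric: str = "total_score",
) -> dict[str, cohort_stats.TestResult]:
    """Per-window two-group comparison of an engraftment metric.

    ``group_of_subject`` maps subject_id -> group label (exactly two levels
    among the scored subjects).
    """
    out: dict[str, cohort_stats.TestResult] = {}
    for window, rows in scores.groupby("window"):
        values = rows.set_index("subject_id")[metric].dropna()
        groups = group_of_subject.reindex(values.index)
        levels = sorted(groups.dropna().unique())
        if len(levels) != 2:
            raise ValueError(f"window {window!r}: need exactly 2 groups, got {levels}")
        x = values[groups == levels[0]].to_numpy()
        y = values[groups == levels[1]].to_numpy()
        if test == "wilcoxon":
            out[str(window)] = cohort_stats.wilcoxon_rank_sum_exact(x, y)
        else:
            raise ValueError(f"unknown test {test!r}")
    return out


def anova_by_arm_and_donor(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    metric: str = "total_score",
) -> dict[str, dict[str, cohort_stats.TestResult]]:
    """Per-window two-way ANOVA of an engraftment metric on arm and donor."""
    recipients = metadata[metadata["role"] == "recipient"].drop_duplicates("subject_id").set_index("subject_id")
    out: dict[str, dict[str, cohort_stats.TestResult]] = {}
    for window, rows in scores.groupby("window"):
        values = rows.set_index("subject_id")[metric].dropna()
        arm = recipients["arm"].reindex(values.index)
        donor = recipients["donor_id"].reindex(values.index)
        res = cohort_stats.two_way_anova(values.to_numpy(), arm, donor)
        out[str(window)] = {"arm": res["factor_a"], "donor": res["factor_b"]}
    return out
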