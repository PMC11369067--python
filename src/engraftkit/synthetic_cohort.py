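"""Synthetic FMT cohort with known ground-truth engraftment.

Emulates the layout of a two-donor, 24-recipient FMT trial: each donor
contributes 13-14 longitudinal stool samples; each recipient has pre-FMT
samples at weeks 0 and 3 and post-FMT samples at weeks 4-8, 10 and 14.

Generative model, per entity:

* A donor draws a species subset from a shared pool and a log-normal base
  composition over it.  Each stool sample is a Dirichlet resample of the base
  (concentration = ``dispersion``) with independent per-species dropout, so
  prevalence varies across samples and the core-species rule is exercised.
* A recipient's baseline shares a configurable fraction of its donor's
  species (the rest drawn from the remaining pool) with its own log-normal
  base.  Pre-FMT samples are noisy resamples of the baseline; the post-FMT
  sample at week w is a noisy resample of the re-closed convex mixture
  ``(1 - lambda_w) * baseline + lambda_w * donor_base``.
* The ground truth records each recipient's mixing fractions and the
  detectably transferred species (donor species outside the baseline whose
  mixture contribution can exceed the detection limit).

The clinical generator is constructive: it works backward from requested
week-10/week-14 response calls to Mayo assessments that the deterministic
classifier maps to exactly those calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .clinical_response import NONE, PARTIAL, REMISSION
from .profiles_io import DEFAULT_TAU

PRE_FMT_WEEKS = (0, 3)
POST_FMT_WEEKS = (4, 5, 6, 7, 8, 10, 14)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for the synthetic cohort; defaults match the
    two-donor, 24-recipient trial layout."""

    n_donors: int = 2
    donor_samples_per_donor: tuple[int, ...] = (13, 14)
    n_recipients: int = 24
    species_pool_size: int = 500
    donor_species_range: tuple[int, int] = (150, 250)
    recipient_baseline_species: int = 120
    donor_recipient_overlap_frac: float = 0.4
    lambda_min: float = 0.05
    lambda_max: float = 0.8
    lambda_schedule: Mapping[str, Mapping[int, float]] | None = None  # subject -> week -> lambda
    dispersion: float = 1000.0
    dropout: float = 0.15
    base_abundance_floor: float = 0.003  # communities are detectable: mean abundance >= 3*tau
    tau: float = DEFAULT_TAU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 1 or self.n_recipients < 1 or self.species_pool_size < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.donor_species_range
        if hi > self.species_pool_size:
            raise ValueError("donor species subset cannot exceed the species pool")
        for frac in (self.donor_recipient_overlap_frac, self.lambda_min, self.lambda_max, self.dropout):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass(frozen=True)
class DonorSim:
    donor_id: str
    species: tuple[str, ...]
    base_profile: pd.Series  # over `species`, sums to 1
    table: pd.DataFrame  # samples x full pool
    weeks: tuple[int, ...]


@dataclass(frozen=True)
class RecipientTruth:
    """Per-recipient generative ground truth."""

    subject_id: str
    donor_id: str
    baseline_species: frozenset[str]
    engrafted_species: frozenset[str]
    lambda_by_week: dict[int, float]


@dataclass(frozen=True)
class CohortSim:
    profiles: pd.DataFrame  # all samples x species pool, rows sum to 1
    metadata: pd.DataFrame
    truth: dict[str, RecipientTruth]
    config: SimulationConfig


def species_pool(cfg: SimulationConfig) -> np.ndarray:
    return np.array([f"sp{i:04d}" for i in range(1, cfg.species_pool_size + 1)])


def donor_label(donor_index: int) -> str:
    # first two donors carry the trial's labels D07/D08
    return f"D{donor_index + 7:02d}"


def _entity_rng(cfg: SimulationConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, *key])


def _lognormal_profile(rng: np.random.Generator, n: int, floor: float, sigma: float = 1.5) -> np.ndarray:
    """Log-normal base composition clipped below at ``floor``.

    The clip encodes that the generator models the *detectable* community:
    every member's expected abundance sits above the detection limit, so
    presence/absence flicker at the threshold comes from sampling noise and
    dropout, not from species that could never be observed reliably.
    """
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    p = raw / raw.sum()
    p = np.maximum(p, floor)
    return p / p.sum()


def _noisy_sample(rng: np.random.Generator, base: np.ndarray, dispersion: float, dropout: float) -> np.ndarray:
    alpha = np.maximum(dispersion * base, 1e-8)
    draw = rng.dirichlet(alpha)
    if dropout > 0:
        keep = rng.random(draw.size) >= dropout
        if not keep.any():  # keep the dominant species rather than emit an all-zero sample
            keep[np.argmax(draw)] = True
        draw = np.where(keep, draw, 0.0)
        draw = draw / draw.sum()
    return draw


def simulate_donor(cfg: SimulationConfig, donor_index: int) -> DonorSim:
    """One donor's species subset, base composition, and longitudinal samples.

    Donor subset sizes are spread across ``donor_species_range`` from richest
    to poorest, so with two donors the first is the higher-diversity one.
    """
    if not 0 <= donor_index < cfg.n_donors:
        raise ValueError(f"donor_index {donor_index} out of range")
    rng = _entity_rng(cfg, 1, donor_index)
    pool = species_pool(cfg)
    lo, hi = cfg.donor_species_range
    if cfg.n_donors == 1:
        size = hi
    else:
        size = int(round(hi - donor_index * (hi - lo) / (cfg.n_donors - 1)))
    species = np.sort(rng.choice(pool, size=size, replace=False))
    base = _lognormal_profile(rng, size, cfg.base_abundance_floor)
    n_samples = cfg.donor_samples_per_donor[donor_index % len(cfg.donor_samples_per_donor)]
    weeks = tuple(range(n_samples))
    rows = np.stack([_noisy_sample(rng, base, cfg.dispersion, cfg.dropout) for _ in weeks])
    donor_id = donor_label(donor_index)
    table = pd.DataFrame(0.0, index=[f"{donor_id}_s{w:02d}" for w in weeks], columns=pool)
    table.loc[:, species] = rows
    return DonorSim(
        donor_id=donor_id,
        species=tuple(species),
        base_profile=pd.Series(base, index=species),
        table=table,
        weeks=weeks,
    )


def recipient_label(recipient_index: int) -> str:
    return f"R{recipient_index + 1:02d}"


def default_lambda(cfg: SimulationConfig, recipient_index: int, week: int) -> float:
    """Default engraftment mixing fraction: constant over post-FMT weeks,
    evenly spaced across recipients from ``lambda_min`` to ``lambda_max``."""
    subject = recipient_label(recipient_index)
    if cfg.lambda_schedule is not None:
        return float(cfg.lambda_schedule[subject][week])
    if cfg.n_recipients == 1:
        return cfg.lambda_max
    step = (cfg.lambda_max - cfg.lambda_min) / (cfg.n_recipients - 1)
    return cfg.lambda_min + recipient_index * step


def simulate_recipient(cfg: SimulationConfig, recipient_index: int, donor: DonorSim) -> tuple[pd.DataFrame, RecipientTruth]:
    """A recipient's pre- and post-FMT samples plus generative ground truth."""
    rng = _entity_rng(cfg, 2, recipient_index)
    pool = species_pool(cfg)
    subject = recipient_label(recipient_index)

    n_overlap = int(round(cfg.donor_recipient_overlap_frac * len(donor.species)))
    n_overlap = min(n_overlap, cfg.recipient_baseline_species)
    overlap = rng.choice(np.array(donor.species), size=n_overlap, replace=False) if n_overlap else np.array([], dtype=object)
    non_donor = np.setdiff1d(pool, np.array(donor.species))
    n_unique = cfg.recipient_baseline_species - n_overlap
    if n_unique > len(non_donor):
        raise ValueError("species pool too small for the requested baseline uniqueness")
    unique = rng.choice(non_donor, size=n_unique, replace=False)
    baseline_species = np.sort(np.concatenate([overlap, unique]))
    baseline_base = pd.Series(
        _lognormal_profile(rng, len(baseline_species), cfg.base_abundance_floor), index=baseline_species
    )

    union = baseline_base.index.union(donor.base_profile.index)
    b = baseline_base.reindex(union, fill_value=0.0).to_numpy()
    d = donor.base_profile.reindex(union, fill_value=0.0).to_numpy()

    rows, sample_ids, weeks = [], [], []
    lam_by_week: dict[int, float] = {}
    for week in PRE_FMT_WEEKS:
        rows.append(_noisy_sample(rng, b, cfg.dispersion, cfg.dropout))
        sample_ids.append(f"{subject}_w{week:02d}")
        weeks.append(week)
    for week in POST_FMT_WEEKS:
        lam = default_lambda(cfg, recipient_index, week)
        lam_by_week[week] = lam
        mix = (1.0 - lam) * b + lam * d
        mix = mix / mix.sum()
        rows.append(_noisy_sample(rng, mix, cfg.dispersion, cfg.dropout))
        sample_ids.append(f"{subject}_w{week:02d}")
        weeks.append(week)

    table = pd.DataFrame(0.0, index=sample_ids, columns=pool)
    table.loc[:, union] = np.stack(rows)

    lam_max = max(lam_by_week.values()) if lam_by_week else 0.0
    transferred = {
        s
        for s in donor.species
        if s not in set(baseline_species) and lam_max * donor.base_profile[s] >= cfg.tau
    }
    truth = RecipientTruth(
        subject_id=subject,
        donor_id=donor.donor_id,
        baseline_species=frozenset(baseline_species),
        engrafted_species=frozenset(transferred),
        lambda_by_week=lam_by_week,
    )
    return table, truth


def default_arm(recipient_index: int) -> str:
    """Deterministic 12/12 arm allocation used by the default cohort."""
    budesonide = {0, 2, 4, 6, 1, 3, 5, 7, 16, 18, 20, 22}
    return "budesonide" if recipient_index in budesonide else "placebo"


def assigned_donor_index(cfg: SimulationConfig, recipient_index: int) -> int:
    # alternate donors so each donor's recipients span the lambda range
    return recipient_index % cfg.n_donors


def simulate_cohort(cfg: SimulationConfig | None = None) -> CohortSim:
    """Full synthetic cohort: donors, recipients, metadata and ground truth."""
    cfg = cfg or SimulationConfig()
    donors = [simulate_donor(cfg, i) for i in range(cfg.n_donors)]
    tables = [d.table for d in donors]
    meta_rows = []
    for d in donors:
        for sample_id, week in zip(d.table.index, d.weeks):
            meta_rows.append((sample_id, d.donor_id, "donor", d.donor_id, week, pd.NA))
    truth: dict[str, RecipientTruth] = {}
    for i in range(cfg.n_recipients):
        donor = donors[assigned_donor_index(cfg, i)]
        table, rt = simulate_recipient(cfg, i, donor)
        tables.append(table)
        truth[rt.subject_id] = rt
        for sample_id, week in zip(table.index, list(PRE_FMT_WEEKS) + list(POST_FMT_WEEKS)):
            meta_rows.append((sample_id, rt.subject_id, "recipient", donor.donor_id, week, default_arm(i)))
    profiles = pd.concat(tables, axis=0)
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "subject_id", "role", "donor_id", "week", "arm"]
    ).set_index("sample_id", drop=False)
    return CohortSim(profiles=profiles, metadata=metadata, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# Constructive clinical generator


def _distribute_partial(pm: int, cap: int = 3) -> tuple[int, int, int]:
    if not 0 <= pm <= 3 * cap:
        raise ValueError(f"partial Mayo {pm} not representable with subscore cap {cap}")
    s1 = min(cap, pm)
    s2 = min(cap, pm - s1)
    s3 = pm - s1 - s2
    return (s1, s2, s3)


def _mayo_row(subject: str, week: int, pm_subscores: tuple[int, int, int], endo: str | None, dropped: bool) -> dict:
    return {
        "subject_id": subject,
        "week": week,
        "stool_frequency": pm_subscores[0],
        "rectal_bleeding": pm_subscores[1],
        "physician_global": pm_subscores[2],
        "endoscopic": endo,
        "dropped_out": dropped,
    }


def simulate_clinical(
    targets: pd.DataFrame,
    baseline_partial: int = 6,
    baseline_endoscopic: str = "2",
) -> pd.DataFrame:
    """Mayo assessments that classify to the requested response calls.

    ``targets`` needs columns ``subject_id``, ``week10``, ``week14`` (each one
    of remission/partial/none) and boolean ``dropped_out``.  The construction
    works backward from each requested call; requests that no valid Mayo
    trajectory can produce (e.g. a partial response from a baseline partial
    Mayo below 3) raise.
    """
    if baseline_partial < 3:
        raise ValueError("baseline partial Mayo < 3 cannot support a partial-response request")
    rows = []
    for _, t in targets.iterrows():
        subject = str(t["subject_id"])
        dropped = bool(t["dropped_out"])
        rows.append(_mayo_row(subject, 0, _distribute_partial(baseline_partial), baseline_endoscopic, dropped))
        if dropped:
            if t["week10"] != NONE or t["week14"] != NONE:
                raise ValueError(f"{subject}: a dropout is a treatment failure; requested calls are unsatisfiable")
            continue
        rows.append(_mayo_row(subject, 10, _follow_up_partial(t["week10"], baseline_partial), None, False))
        pm14, endo14 = _follow_up_full(t["week14"], baseline_partial, baseline_endoscopic)
        rows.append(_mayo_row(subject, 14, pm14, endo14, False))
    return pd.DataFrame.from_records(rows)


def _follow_up_partial(call: str, baseline_pm: int) -> tuple[int, int, int]:
    if call == REMISSION:
        return (1, 0, 1)
    if call == PARTIAL:
        pm = baseline_pm - 3
        if pm <= 2:
            raise ValueError("partial response indistinguishable from remission at this baseline")
        return _distribute_partial(pm)
    if call == NONE:
        return _distribute_partial(max(baseline_pm - 1, 3))
    raise ValueError(f"unknown call {call!r}")


def _follow_up_full(call: str, baseline_pm: int, baseline_endo: str) -> tuple[tuple[int, int, int], str]:
    from .clinical_response import ENDOSCOPIC_LEVELS, ENDOSCOPIC_RANK

    if call == REMISSION:
        return (1, 0, 1), "1a"
    if call == PARTIAL:
        rank = ENDOSCOPIC_RANK[baseline_endo]
        if rank == 0:
            raise ValueError("partial remission needs an endoscopic decrease; baseline already 0")
        pm = baseline_pm - 3
        if pm <= 2:
            raise ValueError("partial remission indistinguishable from remission at this baseline")
        return _distribute_partial(pm), ENDOSCOPIC_LEVELS[rank - 1]
    if call == NONE:
        return _distribute_partial(max(baseline_pm - 1, 3)), baseline_endo
    raise ValueError(f"unknown call {call!r}")


def default_outcome_targets(cfg: SimulationConfig | None = None) -> pd.DataFrame:
    """Response-call allocation mirroring the trial's printed outcome margins.

    Week 10: 10 remission, 2 partial, 12 no response (8 of the 12 responders
    on budesonide).  Week 14: 9 remission, 1 partial, 14 no response, with
    responders split 2 vs 8 across the two donors and 6 vs 4 across arms; two
    never-responders drop out for progressive disease.
    """
    cfg = cfg or SimulationConfig()
    n = cfg.n_recipients
    # 1-based subject numbers; donors alternate (odd -> first donor)
    wk10_remission = {1, 3, 5, 7, 2, 4, 6, 8, 10, 12}
    wk10_partial = {9, 14}
    wk14_remission = {1, 3, 2, 4, 6, 8, 10, 12, 14}
    wk14_partial = {16}
    dropped = {18, 20}
    records = []
    for i in range(n):
        num = i + 1
        if num in dropped:
            wk10 = wk14 = NONE
        else:
            wk10 = REMISSION if num in wk10_remission else PARTIAL if num in wk10_partial else NONE
            wk14 = REMISSION if num in wk14_remission else PARTIAL if num in wk14_partial else NONE
        records.append(
            {
                "subject_id": recipient_label(i),
                "donor_id": donor_label(assigned_donor_index(cfg, i)),
                "arm": default_arm(i),
                "week10": wk10,
                "week14": wk14,
                "dropped_out": num in dropped,
            }
        )
    return pd.DataFrame.from_records(records)
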