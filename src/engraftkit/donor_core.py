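"""Donor core-microbiome derivation and per-recipient donor-derived species sets.

A donor's *core* species are those detected (at or above the detection limit
tau) in at least ``min_samples`` of the donor's longitudinal stool samples.
For each recipient, the *putatively donor-derived* species are the assigned
donor's core species that are absent from every pre-FMT sample of that
recipient; they form the universe within which engraftment is tracked.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .profiles_io import DEFAULT_TAU

#: Prevalence cutoff used in the trial: core membership requires detection in
#: at least 6 of the donor's 13-14 samples.
DEFAULT_MIN_SAMPLES = 6


@dataclass(frozen=True)
class CoreSpeciesSet:
    """A donor's core species and the prevalence rule that produced them."""

    donor_id: str
    species: frozenset[str]
    min_samples: int
    n_donor_samples: int

    def __len__(self) -> int:
        return len(self.species)


@dataclass(frozen=True)
class DonorDerivedSet:
    """Core species of a recipient's donor absent from all its pre-FMT samples."""

    subject_id: str
    donor_id: str
    species: frozenset[str]
    n_pre_fmt_samples_used: int

    def __len__(self) -> int:
        return len(self.species)


def donor_core_species(
    donor_samples: pd.DataFrame,
    tau: float = DEFAULT_TAU,
    min_samples: int | None = DEFAULT_MIN_SAMPLES,
    min_prevalence: float | None = None,
    donor_id: str = "",
) -> CoreSpeciesSet:
    """Species present at >= tau in at least ``min_samples`` donor samples.

    ``min_samples`` is an absolute count and takes precedence; pass
    ``min_samples=None`` with ``min_prevalence`` (a fraction of the donor's
    sample count, rounded up) to use a relative rule instead.
    """
    n = len(donor_samples)
    if n == 0:
        raise ValueError(f"donor {donor_id or '?'}: no samples")
    if min_samples is None:
        if min_prevalence is None:
            raise ValueError("one of min_samples or min_prevalence is required")
        min_samples = max(1, int(-(-min_prevalence * n // 1)))  # ceil
    if min_samples > n:
        raise ValueError(f"min_samples={min_samples} exceeds donor sample count {n}")
    prevalence = (donor_samples >= tau).sum(axis=0)
    members = frozenset(prevalence.index[prevalence >= min_samples])
    return CoreSpeciesSet(donor_id=donor_id, species=members, min_samples=min_samples, n_donor_samples=n)


def core_cumulative_abundance(core: CoreSpeciesSet, donor_samples: pd.DataFrame) -> pd.Series:
    """Per-sample summed relative abundance of the core set in the donor samples.

    In the source trial this was always above 70% — reported as a descriptive
    statistic, never enforced.
    """
    cols = [s for s in donor_samples.columns if s in core.species]
    return donor_samples[cols].sum(axis=1)


def donor_derived_species(
    core: CoreSpeciesSet,
    recipient_pre_samples: pd.DataFrame,
    tau: float = DEFAULT_TAU,
    subject_id: str = "",
) -> DonorDerivedSet:
    """Core species undetected (< tau) in every pre-FMT sample of the recipient.

    The baseline is the union of all pre-FMT samples: a species detected in
    any of them is deemed already present and excluded from engraftment
    tracking.
    """
    if len(recipient_pre_samples) == 0:
        raise ValueError(f"recipient {subject_id or '?'}: no pre-FMT samples; cannot define baseline")
    cols = [s for s in recipient_pre_samples.columns if s in core.species]
    detected = set((recipient_pre_samples[cols] >= tau).any(axis=0).pipe(lambda m: m.index[m]))
    members = frozenset(core.species - detected)
    return DonorDerivedSet(
        subject_id=subject_id,
        donor_id=core.donor_id,
        species=members,
        n_pre_fmt_samples_used=len(recipient_pre_samples),
    )
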