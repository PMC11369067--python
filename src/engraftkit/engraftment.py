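"""Engraftment metrics: SEI, SEF, donor similarity, and the total score.

Three per-subject, per-window metrics quantify complementary facets of donor
microbiota establishment after FMT, all computed over the recipient's
putatively donor-derived species set (see :mod:`engraftkit.donor_core`):

* **SEI** (Species Engraftment Index): the median, over the window's samples,
  of the total relative abundance of donor-derived species detected in the
  sample — how much of the recipient community the donor material displaced.
* **SEF** (Species Engraftment Fraction): the fraction of the donor-derived
  set detected in at least one window sample — the diversity of donor species
  that established, regardless of abundance; in [0, 1].
* **Donor similarity**: compositional distance to the donor is measured with
  the Aitchison distance (Euclidean distance between centred log-ratio
  vectors).  Per window sample the median distance to the donor's samples is
  taken; the window-level median of those is normalized by the same quantity
  at the recipient's week-3 baseline (after pretreatment and lavage, before
  the first infusion) and inverted, so values above 1 mean the recipient
  moved toward the donor.

The *total engraftment score* rescales SEI and similarity so each cohort
median equals the cohort median SEF, then sums the three.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .donor_core import DonorDerivedSet
from .profiles_io import DEFAULT_TAU

__all__ = [
    "ClrConfig",
    "EngraftmentResult",
    "ScoreNormalization",
    "clr_transform",
    "aitchison_distance",
    "aitchison_distance_matrix",
    "sei_per_sample",
    "sei_window",
    "sef_window",
    "donor_similarity",
    "total_engraftment_scores",
]


@dataclass(frozen=True)
class ClrConfig:
    """Zero-replacement policy for the centred log-ratio transform.

    Zeros (true zeros and union-fill zeros) are replaced multiplicatively with
    a pseudocount and the composition re-closed.  By default the pseudocount
    is tied to the detection limit as tau/2: a zero means "below tau", and
    half the detection limit is the natural midpoint imputation.
    """

    pseudocount_mode: str = "fraction_of_tau"  # or "fixed"
    pseudocount_value: float = 0.5  # fraction of tau, or the fixed value itself
    tau: float = DEFAULT_TAU

    @property
    def pseudocount(self) -> float:
        if self.pseudocount_mode == "fraction_of_tau":
            value = self.pseudocount_value * self.tau
        elif self.pseudocount_mode == "fixed":
            value = self.pseudocount_value
        else:
            raise ValueError(f"unknown pseudocount_mode {self.pseudocount_mode!r}")
        if value <= 0:
            raise ValueError("pseudocount must be positive")
        return value


@dataclass
class EngraftmentResult:
    """Per subject x window metric triplet and (once normalized) total score."""

    subject_id: str
    window: str
    sei: float
    sef: float
    similarity: float
    n_samples_in_window: int
    total_score: float = np.nan


@dataclass(frozen=True)
class ScoreNormalization:
    """Cohort-level scales that equalize the three metric medians per window."""

    window: str
    scale_sei: float
    scale_similarity: float
    reference_median: float


def clr_transform(composition: np.ndarray, cfg: ClrConfig | None = None) -> np.ndarray:
    """Centred log-ratio transform with multiplicative zero replacement.

    The input is closed to sum 1 first (the pseudocount lives on the
    relative-abundance scale, so the transform is invariant to a positive
    rescaling of the input), zeros are then replaced by the pseudocount and
    the vector re-closed, and each log component is centred by the mean log.
    The output sums to zero.
    """
    cfg = cfg or ClrConfig()
    x = np.asarray(composition, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("composition must be a 1-D vector of length >= 2")
    if (x < 0).any():
        raise ValueError("composition has negative entries")
    if not (x > 0).any():
        raise ValueError("all-zero composition")
    x = x / x.sum()
    x = np.where(x == 0, cfg.pseudocount, x)
    x = x / x.sum()
    logx = np.log(x)
    return logx - logx.mean()


def aitchison_distance(a: np.ndarray, b: np.ndarray, cfg: ClrConfig | None = None) -> float:
    """Euclidean distance between the clr transforms of two compositions.

    Both compositions must live on the same species universe (union of taxa,
    zero-filled); zeros receive the pseudocount inside :func:`clr_transform`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(clr_transform(a, cfg) - clr_transform(b, cfg)))


def _pair_vectors(row_a: pd.Series, row_b: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Align two thresholded sample rows on the union of their detected species."""
    union = row_a.index[row_a > 0].union(row_b.index[row_b > 0])
    if len(union) < 2:
        raise ValueError("fewer than two species detected across the sample pair")
    return row_a.reindex(union, fill_value=0.0).to_numpy(), row_b.reindex(union, fill_value=0.0).to_numpy()


def sample_pair_distance(row_a: pd.Series, row_b: pd.Series, cfg: ClrConfig | None = None) -> float:
    """Aitchison distance between two samples on the union of detected species."""
    a, b = _pair_vectors(row_a, row_b)
    return aitchison_distance(a, b, cfg)


def aitchison_distance_matrix(table: pd.DataFrame, cfg: ClrConfig | None = None) -> pd.DataFrame:
    """All-pairs Aitchison distances on a common universe (species detected anywhere).

    A shared universe keeps the matrix a true metric, as needed for ordination
    or PERMANOVA across a sample set.
    """
    detected = table.columns[(table > 0).any(axis=0)]
    if len(detected) < 2:
        raise ValueError("fewer than two species detected in the table")
    sub = table[detected].to_numpy()
    clr = np.apply_along_axis(clr_transform, 1, sub, cfg or ClrConfig())
    diff = clr[:, None, :] - clr[None, :, :]
    dm = np.sqrt((diff**2).sum(axis=2))
    return pd.DataFrame(dm, index=table.index, columns=table.index)


def sei_per_sample(sample: pd.Series, dd: DonorDerivedSet, tau: float = DEFAULT_TAU) -> float:
    """Total relative abundance of donor-derived species detected in a sample."""
    if not dd.species:
        return 0.0
    cols = [s for s in sample.index if s in dd.species]
    vals = sample[cols]
    return float(vals[vals >= tau].sum())


def sei_window(window_samples: pd.DataFrame, dd: DonorDerivedSet, tau: float = DEFAULT_TAU) -> float:
    """Median per-sample SEI over a subject's samples in a window."""
    if len(window_samples) == 0:
        raise ValueError("no samples in window")
    values = [sei_per_sample(row, dd, tau) for _, row in window_samples.iterrows()]
    return float(np.median(values))


def sef_window(window_samples: pd.DataFrame, dd: DonorDerivedSet, tau: float = DEFAULT_TAU) -> float:
    """Fraction of the donor-derived set detected in >= 1 sample of the window."""
    if len(window_samples) == 0:
        raise ValueError("no samples in window")
    if not dd.species:
        raise ValueError(f"subject {dd.subject_id}: empty donor-derived set; SEF undefined")
    cols = [s for s in window_samples.columns if s in dd.species]
    detected = int((window_samples[cols] >= tau).any(axis=0).sum())
    return detected / len(dd.species)


def _distance_to_donor(row: pd.Series, donor_samples: pd.DataFrame, cfg: ClrConfig | None) -> float:
    dists = [sample_pair_distance(row, drow, cfg) for _, drow in donor_samples.iterrows()]
    return float(np.median(dists))


def donor_similarity(
    window_samples: pd.DataFrame,
    baseline_sample: pd.Series,
    donor_samples: pd.DataFrame,
    cfg: ClrConfig | None = None,
    pooled: bool = False,
) -> float:
    """Baseline-normalized reciprocal Aitchison distance to the donor.

    For each window sample, the distance to the donor is the median Aitchison
    distance to the donor's samples; the window distance is the median of
    these per-timepoint values (or, with ``pooled=True``, the median over all
    recipient-sample x donor-sample pairs).  The similarity returned is
    ``baseline_distance / window_distance``, the reciprocal of the
    baseline-normalized distance, so >1 means the recipient moved toward the
    donor relative to its pre-FMT state.
    """
    if len(window_samples) == 0:
        raise ValueError("no samples in window")
    if len(donor_samples) == 0:
        raise ValueError("donor has no samples")
    baseline = _distance_to_donor(baseline_sample, donor_samples, cfg)
    if baseline == 0:
        raise ValueError("degenerate baseline: recipient identical to donor before FMT")
    if pooled:
        all_d = [
            sample_pair_distance(rrow, drow, cfg)
            for _, rrow in window_samples.iterrows()
            for _, drow in donor_samples.iterrows()
        ]
        window_distance = float(np.median(all_d))
    else:
        per_t = [_distance_to_donor(row, donor_samples, cfg) for _, row in window_samples.iterrows()]
        window_distance = float(np.median(per_t))
    if window_distance == 0:
        raise ValueError("degenerate window: recipient identical to donor")
    return baseline / window_distance


def total_engraftment_scores(results: list[EngraftmentResult]) -> tuple[list[EngraftmentResult], dict[str, ScoreNormalization]]:
    """Combine SEI, SEF and similarity into a total score per subject x window.

    Within each window, subjects with a complete metric triplet define the
    cohort medians; SEI and similarity are rescaled so their medians equal the
    median SEF, and the three rescaled metrics are summed.  A metric whose
    cohort median is zero cannot be rescaled; its contribution is zeroed with
    a warning.  Scales are returned for reproducibility.
    """
    norms: dict[str, ScoreNormalization] = {}
    by_window: dict[str, list[EngraftmentResult]] = {}
    for r in results:
        by_window.setdefault(r.window, []).append(r)
    for window, rs in by_window.items():
        complete = [r for r in rs if np.isfinite(r.sei) and np.isfinite(r.sef) and np.isfinite(r.similarity)]
        if len(complete) < 2:
            raise ValueError(f"window {window!r}: need >= 2 subjects with complete metric triplets")
        med_sei = float(np.median([r.sei for r in complete]))
        med_sef = float(np.median([r.sef for r in complete]))
        med_sim = float(np.median([r.similarity for r in complete]))
        scale_sei = _scale("SEI", med_sef, med_sei, window)
        scale_sim = _scale("similarity", med_sef, med_sim, window)
        norms[window] = ScoreNormalization(
            window=window, scale_sei=scale_sei, scale_similarity=scale_sim, reference_median=med_sef
        )
        for r in rs:
            r.total_score = r.sef + scale_sei * r.sei + scale_sim * r.similarity
    return results, norms


def _scale(name: str, reference_median: float, metric_median: float, window: str) -> float:
    if metric_median == 0:
        warnings.warn(
            f"window {window!r}: cohort median {name} is 0; its contribution to the total score is dropped",
            stacklevel=3,
        )
        return 0.0
    return reference_median / metric_median
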