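"""Coupling factors: how each lipid-binding event modulates the protein-protein affinity.

The coupling factor for the i-th lipid-binding event compares lipid binding
to the complex with lipid binding to the free channel.  Two conventions are
provided:

* ``lipid_event`` (default): ``alpha_i = K_A,AGLi / K_A,ALi``, which by
  thermodynamic cycle closure equals ``K_A,ALiG / K_A,AL(i-1)G`` — the fold
  change in partner affinity caused by the i-th bound lipid.  Defined for
  every event i >= 1.
* ``verbatim``: ``alpha_i = K_A,AGLi / K_A,AGL(i-1)``, the ratio of
  consecutive complex lipid-binding constants.  The denominator does not
  exist for i = 1, so this convention is defined for i >= 2 only.

alpha > 1 is positive allosteric modulation (lipid binding strengthens the
protein-protein interaction), alpha ~ 1 neutral, alpha < 1 negative.
Classification uses a z * s.e.m. band around 1 (z = 1 by default): an event
is called positive/negative only when its error bar clears 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .equilibrium import BindingModelParams, ValidationError, derived_agl_constants
from .titration import FitResult, aggregate_replicates

__all__ = [
    "CouplingFactorSet",
    "coupling_factors",
    "coupling_factors_from_fit",
    "classify_allostery",
    "coupling_trend",
]

CONVENTIONS = ("lipid_event", "verbatim")


@dataclass(frozen=True)
class CouplingFactorSet:
    """Per-lipid-binding-event coupling factors with uncertainty and class."""

    alpha: np.ndarray
    alpha_sem: np.ndarray
    convention: str = "lipid_event"
    classification: tuple[str, ...] = field(default_factory=tuple)
    events: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        object.__setattr__(self, "alpha_sem", np.asarray(self.alpha_sem, dtype=float))
        if np.any(self.alpha <= 0):
            raise ValidationError("coupling factors must be positive")
        if self.events.size == 0:
            start = 1 if self.convention == "lipid_event" else 2
            object.__setattr__(
                self, "events", np.arange(start, start + self.alpha.size)
            )


def coupling_factors(
    params: BindingModelParams, convention: str = "lipid_event"
) -> CouplingFactorSet:
    """Coupling factors of one fitted parameter set (no replicate uncertainty)."""
    if convention not in CONVENTIONS:
        raise ValidationError(f"unknown convention {convention!r}")
    k_agl = derived_agl_constants(params)
    if convention == "lipid_event":
        alpha = k_agl / params.k_al
    else:
        if params.n_max < 2:
            raise ValidationError(
                "verbatim convention is undefined at i=1; it needs n_max >= 2"
            )
        alpha = k_agl[1:] / k_agl[:-1]
    return CouplingFactorSet(
        alpha=alpha, alpha_sem=np.full(alpha.size, np.nan), convention=convention
    )


def classify_allostery(
    alpha: float, sem: float, z: float = 1.0, neutral_margin: float = 0.05
) -> str:
    """Classify one coupling factor as positive / neutral / negative.

    Neutral if the coupling factor is practically equivalent to 1
    (``|alpha - 1| <= neutral_margin``) or if the ``z * sem`` error bar
    overlaps 1; otherwise positive (> 1) or negative (< 1).  The equivalence
    margin guards against over-calling tiny deviations when replicate
    scatter happens to be small: a precise fit of a genuinely neutral system
    can land a few (small) standard errors away from exactly 1, and a 5%
    change in an association-constant ratio is below what this kind of
    titration resolves as a real allosteric effect.  A NaN s.e.m. (single
    replicate) is treated as 0.
    """
    if np.isnan(sem):
        sem = 0.0
    if sem < 0:
        raise ValidationError("s.e.m. must be >= 0")
    if abs(alpha - 1.0) <= neutral_margin:
        return "neutral"
    if alpha - z * sem > 1.0:
        return "positive"
    if alpha + z * sem < 1.0:
        return "negative"
    return "neutral"


def coupling_factors_from_fit(
    fit: FitResult,
    convention: str = "lipid_event",
    z: float = 1.0,
    neutral_margin: float = 0.05,
) -> CouplingFactorSet:
    """Replicate-aggregated coupling factors from a global fit.

    Coupling factors are computed per replicate from that replicate's fitted
    constants, then summarised as mean +/- s.e.m. and classified.
    """
    per_rep = np.array(
        [coupling_factors(rf.params, convention).alpha for rf in fit.per_replicate]
    )
    stats = [aggregate_replicates(per_rep[:, j]) for j in range(per_rep.shape[1])]
    alpha = np.array([m for m, _ in stats])
    sem = np.array([s for _, s in stats])
    classes = tuple(
        classify_allostery(a, s, z=z, neutral_margin=neutral_margin)
        for a, s in zip(alpha, sem)
    )
    return CouplingFactorSet(
        alpha=alpha, alpha_sem=sem, convention=convention, classification=classes
    )


def coupling_trend(alpha_vs_event) -> float:
    """Ordinary least-squares slope of alpha against the binding-event index.

    Accepts an iterable of ``(i, alpha_i)`` pairs; quantifies the per-event
    increase (or decrease) in coupling.
    """
    pairs = np.asarray(list(alpha_vs_event), dtype=float)
    if pairs.ndim != 2 or pairs.shape[0] < 2:
        raise ValidationError("coupling_trend needs >= 2 (event, alpha) points")
    slope, _ = np.polyfit(pairs[:, 0], pairs[:, 1], 1)
    return float(slope)
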