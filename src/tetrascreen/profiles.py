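"""Cell-cycle class profiles and knockdown effects.

A well's population is described by a probability vector over seven states:
the six classified ploidy/cell-cycle classes plus a FUCCI-negative state
(cells expressing neither sensor, excluded from downstream abundances).
Knockdown effects act on the log-odds of the proliferating-tetraploid
classes (4CS, 8CG2) against everything else, which encodes the "TP53-like"
phenotype — more tetraploid cells entering S phase and reaching G2 — with a
single scalar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: The six classes contributing to well abundances, in canonical order.
SIX_CLASSES: tuple[str, ...] = ("2CG1", "2CS", "4CG2", "4CG1", "4CS", "8CG2")

#: All generator states: six classes plus the FUCCI-negative state.
STATE_NAMES: tuple[str, ...] = SIX_CLASSES + ("FUCCI_neg",)

#: Classes whose joint log-odds a knockdown effect shifts.
PROLIFERATING_TETRAPLOID: tuple[str, ...] = ("4CS", "8CG2")

_EFFECT_MASK = np.array([name in PROLIFERATING_TETRAPLOID for name in STATE_NAMES])

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class ClassProfile:
    """Probability vector over the seven population states.

    Parameters
    ----------
    probs
        Length-7 array ordered as :data:`STATE_NAMES`.  Must be non-negative
        and sum to 1 within 1e-12.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (len(STATE_NAMES),):
            raise ValueError(f"profile must have {len(STATE_NAMES)} entries, got {p.shape}")
        if np.any(p < 0):
            raise ValueError("class probabilities must be non-negative")
        if abs(p.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"class probabilities must sum to 1 (got {p.sum()!r})")
        object.__setattr__(self, "probs", p)

    def __getitem__(self, state: str) -> float:
        return float(self.probs[STATE_NAMES.index(state)])

    def as_dict(self) -> dict[str, float]:
        return {name: float(p) for name, p in zip(STATE_NAMES, self.probs)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ClassProfile":
        missing = set(STATE_NAMES) - set(d)
        if missing:
            raise ValueError(f"missing states: {sorted(missing)}")
        return cls(np.array([d[name] for name in STATE_NAMES], dtype=float))

    @property
    def tetraploid_fraction(self) -> float:
        """Mass of the binucleated-tetraploid classes (4CG1 + 4CS + 8CG2)."""
        return self["4CG1"] + self["4CS"] + self["8CG2"]


def dcd_default_profile() -> ClassProfile:
    """Baseline population after transient actin-polymerization inhibition.

    Emulates a mixed population of roughly 65% binucleated tetraploid and
    30% diploid cells, with most cells of either ploidy cycling, plus a 5%
    FUCCI-negative fraction.  Within each ploidy compartment the split over
    G1/S/G2 reflects an actively cycling population with the largest mass in
    G1.
    """
    return ClassProfile.from_dict(
        {
            "2CG1": 0.12,
            "2CS": 0.12,
            "4CG2": 0.06,
            "4CG1": 0.30,
            "4CS": 0.23,
            "8CG2": 0.12,
            "FUCCI_neg": 0.05,
        }
    )


def apply_knockdown_effect(base: ClassProfile, effect_size: float) -> ClassProfile:
    """Shift the joint log-odds of the proliferating-tetraploid classes.

    Multiplies the probabilities of 4CS and 8CG2 by ``exp(effect_size)`` and
    renormalizes, i.e. adds ``effect_size`` to the log-odds of
    {4CS, 8CG2} versus all other states.  ``effect_size == 0`` returns the
    base profile unchanged; ``+inf`` concentrates all mass on the shifted
    classes in proportion to their base probabilities (when they carry any
    mass at all — a base with zero mass there is returned unchanged).
    """
    if math.isnan(effect_size):
        raise ValueError("effect_size must not be NaN")
    if effect_size == 0.0:
        return base
    p = base.probs
    shifted_mass = p[_EFFECT_MASK].sum()
    if math.isinf(effect_size):
        if effect_size > 0:
            if shifted_mass == 0.0:
                return base
            w = np.where(_EFFECT_MASK, p, 0.0)
        else:
            if shifted_mass == 1.0:
                return base
            w = np.where(_EFFECT_MASK, 0.0, p)
        return ClassProfile(w / w.sum())
    w = p * np.where(_EFFECT_MASK, math.exp(effect_size), 1.0)
    return ClassProfile(w / w.sum())
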