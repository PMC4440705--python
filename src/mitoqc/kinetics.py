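"""Propensity and selectivity functions of the quality-control model.

All reaction channels share one phenomenological ingredient: the OXPHOS
defect function ``s(R) = R^m / (K^m + R^m)``, a Hill sigmoid of a
mitochondrion's mutant fraction R.  ``K`` is the heteroplasmy threshold
midpoint (``s(K) = 0.5``) and ``m`` sets the sharpness of the phenotypic
threshold.  The channels are:

* **mitophagy** of mitochondrion i:  ``a_D = k_D (r_D_max s(R_i) + 1)`` —
  basal turnover amplified up to ``(r_D_max + 1)``-fold for defective
  mitochondria (selective mitophagy).
* **replication** of a nucleoid: basal per-nucleoid rate ``a_R0 / N_ss``
  amplified by the retrograde response ``(r_R_max s(Rbar) + 1)`` where
  ``Rbar`` is the cell's average mitochondrial mutant fraction; mutant
  nucleoids carry an extra replicative-advantage factor ``k_R >= 1``.
* **fusion** of a feasible pair (i, j):  ``a_fus = a_fusion0 r(R_i) r(R_j)``
  with the selectivity factor ``r(R) = 1 - r_fusion_max s(R)`` — defective
  mitochondria are excluded from fusion (selective fusion).
* **fission** of mitochondrion i with N_i nucleoids:
  ``a_fis = V_F_max N_i^n / (K_F^n + N_i^n)`` — content-dependent but not
  mutation-selective.  Mitochondria with fewer than 2 nucleoids cannot
  split (propensity clamped to 0).

``ff_scale`` multiplies both ``a_fusion0`` and ``V_F_max``, changing the
fusion-fission frequency while preserving their ratio; ``ff_scale = 1``
corresponds to a nucleoid mixing time constant of 7.5 days.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

from .state import Mitochondrion

__all__ = [
    "QCParams",
    "oxphos_defect",
    "mitophagy_propensity",
    "replication_propensity_per_nucleoid",
    "fusion_selectivity",
    "fusion_pair_propensity",
    "fission_propensity",
]

#: Mixing time constant (days) realised by ``ff_scale = 1``.
TAU_NOMINAL = 7.5


@dataclass(frozen=True)
class QCParams:
    """Rate and selectivity parameters of the quality-control model.

    Defaults are the nominal parameter set.  Units: rates in day^-1,
    thresholds and selectivities dimensionless fractions.
    """

    # OXPHOS defect thresholds (midpoints) per process, shared sharpness m.
    K_D: float = 0.75
    K_fusion: float = 0.75
    K_R: float = 0.75
    m: float = 11.0
    # Mitophagy: basal rate (ln2 / 30-day half-life) and selectivity strength.
    k_D: float = 0.023
    r_D_max: float = 5.0
    # Replication: basal cell-level propensity, retrograde amplification,
    # mutant replicative advantage; N_ss converts a_R0 to a per-nucleoid rate.
    a_R0: float = 7.4
    r_R_max: float = 9.0
    k_R: float = 1.0
    N_ss: int = 320
    # Fusion: basal pairwise propensity and maximum selective reduction.
    a_fusion0: float = 0.123
    r_fusion_max: float = 0.8
    # Fission: Hill dependence on nucleoid content.
    V_F_max: float = 8.6e4
    K_F: float = 30.0
    n: float = 6.0
    # Common fusion+fission frequency multiplier (1 <=> tau = 7.5 days).
    ff_scale: float = 1.0
    # Retrograde input: mean of R_M^mito over mitochondria (default) or the
    # cell nucleoid fraction R_M^cell.
    retrograde_uses_cell_fraction: bool = False

    def __post_init__(self) -> None:
        errors = []
        for name in ("k_D", "r_D_max", "a_R0", "r_R_max", "a_fusion0", "V_F_max",
                     "K_F", "n", "m"):
            if getattr(self, name) < 0:
                errors.append(f"{name} must be >= 0")
        for name in ("K_D", "K_fusion", "K_R"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                errors.append(f"{name} must lie in (0, 1]")
        if not 0.0 <= self.r_fusion_max <= 1.0:
            errors.append("r_fusion_max must lie in [0, 1]")
        if self.k_R < 1.0:
            errors.append("k_R must be >= 1")
        if self.ff_scale <= 0.0:
            errors.append("ff_scale must be > 0")
        if self.N_ss < 1:
            errors.append("N_ss must be >= 1")
        if errors:
            raise ValueError("invalid parameters: " + "; ".join(errors))

    # -- derived quantities --------------------------------------------
    @property
    def a_fusion_eff(self) -> float:
        """Pairwise fusion propensity including the frequency multiplier."""
        return self.ff_scale * self.a_fusion0

    @property
    def V_F_eff(self) -> float:
        """Maximum fission propensity including the frequency multiplier."""
        return self.ff_scale * self.V_F_max

    @property
    def alpha(self) -> float:
        """Fixed fission:fusion rate-constant ratio (ff_scale invariant)."""
        return self.V_F_max / self.a_fusion0

    @property
    def a_R0_per_nucleoid(self) -> float:
        """Basal replication rate per nucleoid (= k_D at the nominal set)."""
        return self.a_R0 / self.N_ss

    def with_(self, **kwargs) -> "QCParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def with_threshold(self, K: float) -> "QCParams":
        """Set all three defect-threshold midpoints equally."""
        return self.with_(K_D=K, K_fusion=K, K_R=K)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def nominal(cls) -> "QCParams":
        """The nominal parameter set (the dataclass defaults, spelled out)."""
        return cls()


def oxphos_defect(R: float, K: float, m: float) -> float:
    """Degree of OXPHOS dysfunction of a mitochondrion with mutant fraction R.

    ``s(R) = R^m / (K^m + R^m)``; ``s(0) = 0``, ``s(K) = 0.5``, strictly
    increasing, approaching (but not reaching) 1 at ``R = 1``.
    """
    if not 0.0 <= R <= 1.0:
        raise ValueError("mutant fraction must lie in [0, 1]")
    if R == 0.0:
        return 0.0
    rm = R**m
    return rm / (K**m + rm)


def mitophagy_propensity(R_mito: float, p: QCParams) -> float:
    """Removal propensity of a mitochondrion with mutant fraction ``R_mito``."""
    return p.k_D * (p.r_D_max * oxphos_defect(R_mito, p.K_D, p.m) + 1.0)


def replication_propensity_per_nucleoid(is_mutant: bool, Rbar: float, p: QCParams) -> float:
    """Replication propensity of one nucleoid given the retrograde input ``Rbar``.

    The cell-level total over all WT nucleoids of a homoplasmic WT cell at
    ``N_ss`` nucleoids equals the basal rate ``a_R0``.
    """
    retro = p.r_R_max * oxphos_defect(Rbar, p.K_R, p.m) + 1.0
    rate = p.a_R0_per_nucleoid * retro
    return p.k_R * rate if is_mutant else rate


def fusion_selectivity(R_mito: float, p: QCParams) -> float:
    """Fusion participation factor ``r(R) = 1 - r_fusion_max s(R)`` in [0, 1]."""
    return 1.0 - p.r_fusion_max * oxphos_defect(R_mito, p.K_fusion, p.m)


def fusion_pair_propensity(mi: Mitochondrion, mj: Mitochondrion, p: QCParams) -> float:
    """Fusion propensity of a feasible (same/adjacent compartment) pair.

    The caller is responsible for enumerating only feasible pairs; this
    function evaluates the rate law only.
    """
    ri = fusion_selectivity(mi.mutant_fraction, p)
    rj = fusion_selectivity(mj.mutant_fraction, p)
    return p.a_fusion_eff * ri * rj


def fission_propensity(mi: Mitochondrion, p: QCParams) -> float:
    """Fission propensity of a mitochondrion from its total nucleoid content.

    Clamped to 0 below 2 nucleoids: both fission daughters must hold at
    least one nucleoid.  (The raw Hill value at a content of 1 would be
    ~1.2e-4 per day at nominal parameters — negligible.)
    """
    total = mi.total
    if total < 1:
        raise ValueError("fission propensity undefined for an empty mitochondrion")
    if total < 2:
        return 0.0
    tn = float(total) ** p.n
    return p.V_F_eff * tn / (p.K_F**p.n + tn)
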