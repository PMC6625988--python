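"""Synthetic screens and xenograft datasets with the structure the analysis assumes.

The screen generator plants known ground truth so every downstream stage is
testable without real data:

* single-drug responses follow the median-effect model
  fa/(1−fa) = (D/Dm)^m with per-drug (m, Dm);
* mixture responses are generated from the combination-index identity
  itself: fa solves Σ_j D_j / [Dm_j·(fa/(1−fa))^(1/m_j)] = γ, where the
  interaction parameter γ is 1 for Loewe additivity, <1 for synergy and
  >1 for antagonism — so a correct analysis recovers CI = γ exactly on
  noise-free data (a Bliss-independence generator is available by flag but
  is not the default, since the CI framework is Loewe-based);
* measurement noise is additive Gaussian on percent viability, truncated
  below at 0 but not clamped at 100 (keeps the control mean unbiased), and
  inflated per droplet by √(mean_cells/actual_cells) with
  actual_cells ~ Poisson(mean_cells) — the counting statistics of seeding
  ~100 cells in a 200-nl droplet.

The tumor generator grows each mouse exponentially,
V(t) = V0·exp[(growth − inhibition)·t], and reports two orthogonal caliper
diameters around the mean diameter l = (6V/π)^(1/3) with Gaussian caliper
noise (negative draws are resampled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .design import ConditionSet
from .dose_response import ViabilityTable
from .errors import ConfigError, NumericalError
from .invivo import TumorMeasurements

__all__ = [
    "TrueDrugParams",
    "ScreenSimConfig",
    "TumorSimConfig",
    "fraction_affected_single",
    "fraction_affected_mixture",
    "simulate_screen",
    "simulate_single_drug_titration",
    "simulate_tumor_growth",
]

_FA_LO, _FA_HI = 1e-9, 1.0 - 1e-9


@dataclass(frozen=True)
class TrueDrugParams:
    """Ground-truth median-effect parameters for one simulated drug."""

    name: str
    m_slope: float
    dm: float  # μg/ml

    def __post_init__(self):
        if self.m_slope <= 0 or self.dm <= 0:
            raise ConfigError(f"{self.name}: m_slope and Dm must be positive")


@dataclass
class ScreenSimConfig:
    design: ConditionSet
    true_params: list[TrueDrugParams]
    interaction_gamma: float = 1.0  # 1 = Loewe additive, <1 synergy, >1 antagonism
    replicates: int = 3
    noise_sd: float = 5.0  # percentage points of viability
    mean_cells_per_droplet: int = 100
    mechanism: str = "loewe"  # or "bliss"
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.interaction_gamma <= 0:
            raise ConfigError("interaction_gamma must be positive")
        if self.mechanism not in ("loewe", "bliss"):
            raise ConfigError(f"unknown mechanism '{self.mechanism}'")
        have = {p.name for p in self.true_params}
        missing = [n for n in self.design.drug_names if n not in have]
        if missing:
            raise ConfigError(f"missing TrueDrugParams for drug(s): {missing}")

    @property
    def params_by_name(self) -> dict[str, TrueDrugParams]:
        return {p.name: p for p in self.true_params}


def fraction_affected_single(dose: float, params: TrueDrugParams) -> float:
    """fa at one dose of one drug: fa = 1/(1 + (Dm/D)^m); 0 at D = 0."""
    if dose <= 0:
        return 0.0
    return 1.0 / (1.0 + (params.dm / dose) ** params.m_slope)


def _loewe_objective(fa: float, doses: dict[str, float], params: dict[str, TrueDrugParams]) -> float:
    total = 0.0
    ratio = fa / (1.0 - fa)
    for name, d in doses.items():
        if d > 0:
            p = params[name]
            total += d / (p.dm * ratio ** (1.0 / p.m_slope))
    return total


def fraction_affected_mixture(
    doses: dict[str, float],
    params: dict[str, TrueDrugParams],
    gamma: float = 1.0,
    mechanism: str = "loewe",
) -> float:
    """Effect of a dose mixture under the chosen combination mechanism.

    Loewe: fa is the root of Σ_j D_j/Dx_j(fa) = γ, bracketed on
    (1e−9, 1−1e−9) — the sum is strictly decreasing in fa, so the root is
    unique.  Bliss: fa = 1 − Π_j (1 − fa_j) with per-drug doses scaled by γ.
    """
    active = {k: v for k, v in doses.items() if v > 0}
    if not active:
        return 0.0
    if mechanism == "bliss":
        fu = 1.0
        for name, d in active.items():
            fu *= 1.0 - fraction_affected_single(d * (1.0 / gamma), params[name])
        return 1.0 - fu
    if len(active) == 1:  # single drug: closed form, γ rescales the dose
        (name, d), = active.items()
        return fraction_affected_single(d / gamma, params[name])
    f_lo = _loewe_objective(_FA_LO, active, params) - gamma
    f_hi = _loewe_objective(_FA_HI, active, params) - gamma
    if not (f_lo > 0 > f_hi):
        raise NumericalError(
            f"mixture root not bracketed: f({_FA_LO})={f_lo:.3g}, f({_FA_HI})={f_hi:.3g} "
            f"for doses {active}"
        )
    return float(
        optimize.brentq(
            lambda fa: _loewe_objective(fa, active, params) - gamma,
            _FA_LO,
            _FA_HI,
            xtol=1e-12,
            rtol=1e-14,
        )
    )


def simulate_screen(cfg: ScreenSimConfig) -> ViabilityTable:
    """Simulate the full factorial screen; reproducible under a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    params = cfg.params_by_name
    rows = []
    for cond in cfg.design.conditions:
        if cond.role == "control":
            fa = 0.0
        elif cond.role == "single":
            # gamma only perturbs mixtures: singles define the reference curves
            (name, d), = ((k, v) for k, v in cond.doses.items() if v > 0)
            fa = fraction_affected_single(d, params[name])
        else:
            fa = fraction_affected_mixture(
                cond.doses, params, gamma=cfg.interaction_gamma, mechanism=cfg.mechanism
            )
        true_v = 100.0 * (1.0 - fa)
        for rep in range(1, cfg.replicates + 1):
            cells = int(rng.poisson(cfg.mean_cells_per_droplet))
            while cells < 1:  # empty droplet: re-seed (documented)
                cells = int(rng.poisson(cfg.mean_cells_per_droplet))
            scale = np.sqrt(cfg.mean_cells_per_droplet / cells)
            v = true_v + rng.normal(0.0, cfg.noise_sd * scale) if cfg.noise_sd > 0 else true_v
            rows.append(
                {"condition_id": cond.id, "replicate": rep, "viability": max(0.0, v)}
            )
    return ViabilityTable(records=pd.DataFrame(rows), design=cfg.design)


def simulate_single_drug_titration(
    params: TrueDrugParams,
    doses=None,
    replicates: int = 3,
    noise_sd: float = 5.0,
    mean_cells_per_droplet: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Dedicated dose–response titration for one drug (doses, viabilities).

    Emulates the single-agent IC50 experiment run alongside a combination
    screen: by default 8 log-spaced doses spanning 1/30× to 30× the drug's
    active range (a titration centred after a pilot), plus the zero-dose
    control, with the same droplet noise model as the screen.  A factorial
    screen with only two positive levels per drug cannot anchor a reliable
    median-effect fit for a weak drug under noise; this can.
    """
    rng = np.random.default_rng(seed)
    if doses is None:
        doses = np.concatenate([[0.0], np.geomspace(params.dm / 30, params.dm * 30, 8)])
    doses = np.asarray(doses, dtype=float)
    all_d, all_v = [], []
    for d in doses:
        fa = fraction_affected_single(float(d), params)
        true_v = 100.0 * (1.0 - fa)
        for _ in range(replicates):
            cells = int(rng.poisson(mean_cells_per_droplet))
            while cells < 1:
                cells = int(rng.poisson(mean_cells_per_droplet))
            scale = np.sqrt(mean_cells_per_droplet / cells)
            v = true_v + rng.normal(0.0, noise_sd * scale) if noise_sd > 0 else true_v
            all_d.append(float(d))
            all_v.append(max(0.0, v))
    return np.array(all_d), np.array(all_v)


@dataclass
class TumorSimConfig:
    """Groups are (label, growth_rate /day, inhibition_factor /day)."""

    groups: list[tuple[str, float, float]]
    n_mice: int = 4
    measurement_days: tuple[float, ...] = (0, 3, 5, 7, 9, 11, 13, 15)
    initial_volume: float = 100.0  # mm³, palpable subcutaneous tumor
    diameter_noise_sd: float = 0.3  # mm caliper error
    seed: int = 0

    def __post_init__(self):
        if self.n_mice < 1:
            raise ConfigError("n_mice must be >= 1")
        days = tuple(float(d) for d in self.measurement_days)
        if days != tuple(sorted(days)) or days[0] != 0:
            raise ConfigError("measurement_days must be sorted and start at 0")
        object.__setattr__(self, "measurement_days", days)


def simulate_tumor_growth(cfg: TumorSimConfig) -> TumorMeasurements:
    """Exponential growth per mouse with treatment-dependent inhibition."""
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for label, growth, inhibition in cfg.groups:
        net = growth - inhibition  # negative net rate = shrinkage, allowed
        for i in range(1, cfg.n_mice + 1):
            mouse = f"{label}-{i:02d}"
            for day in cfg.measurement_days:
                v = cfg.initial_volume * np.exp(net * day)
                l = (6.0 * v / np.pi) ** (1.0 / 3.0)
                a = b = l
                if cfg.diameter_noise_sd > 0:
                    a = rng.normal(l, cfg.diameter_noise_sd)
                    while a <= 0:
                        a = rng.normal(l, cfg.diameter_noise_sd)
                    b = rng.normal(l, cfg.diameter_noise_sd)
                    while b <= 0:
                        b = rng.normal(l, cfg.diameter_noise_sd)
                rows.append(
                    {
                        "mouse_id": mouse,
                        "group": label,
                        "day": day,
                        "diameter_a": float(a),
                        "diameter_b": float(b),
                    }
                )
    return TumorMeasurements(records=pd.DataFrame(rows))
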