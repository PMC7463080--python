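"""Generative simulator of a five-level restricted-feeding
comparative-slaughter trial with known ground-truth energy parameters.

The simulator emulates the study design behind the bundled reference
dataset: graded feeding levels (ad libitum down to 55% of ad libitum), a
14-day balance period from age 7 d to 21 d, a baseline slaughter group at
the start, a mid-period slaughter in the ad-libitum line, marker mass
balance in the excreta, and multiplicative log-normal assay noise.

Generative energy laws
----------------------
Two heat-production modes exist because the two maintenance regressions of
the estimation chain (log-linear HP on MEI; linear RE on MEI) are mutually
inconsistent as exact models; each mode makes one of them exactly
recoverable:

* ``linear_re``: RE = K_g x (MEI - ME_m) per kg BW^0.75 per day, plus a
  deterministic zero-sum replicate offset (see below). K_g, ME_m, NE_g,
  K_p and K_f are exactly recoverable; the log-extrapolated NE_m carries a
  small, documented model-discordance bias.
* ``exponential``: HP = NE_m x 10^(b x MEI) per kg BW^0.75 per day. The
  fasting heat production NE_m and the log slope b are exactly
  recoverable; K_g/ME_m become effective quantities.

The laws are imposed exactly on the balance-period aggregate scale using
the midpoint metabolic-weight convention - the same scale on which the
analysis pipeline estimates the parameters - and the daily trajectory
distributes the period totals (weight gain dW = RE/NE_g each day).

Replicate offsets
-----------------
With a partition driven by MEI alone, RE_p and RE_f are exact affine
functions of MEI and therefore collinear, so the Boekholt regression would
be rank-deficient on noiseless data. The simulator adds a deterministic
zero-sum replicate offset e_r to RE (an alternating within-level pattern,
orthogonalized against [1, MEI]), emulating animal-to-animal variation
while leaving the RE-MEI least-squares fit exact. The partition (RE_p,
RE_f) then solves, per replicate, the pair of constraints

    RE_p + RE_f = RE
    RE_p / K_p + RE_f / K_f = MEI - b0

so the Boekholt plane holds exactly with non-collinear predictors.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .ame import ame_table
from .balance import EnergyConstants, balance_table
from .exceptions import SimulationError, ValidationError
from .model import FactorialNEModel, fit_efficiency, fit_growth, fit_maintenance
from .tables import (
    CarcassRecord,
    DietAssay,
    ExcretaAssay,
    IntakeRecord,
    TrialTables,
)

_DEFAULT_LEVELS = (1.00, 0.85, 0.75, 0.65, 0.55)
_DEFAULT_LABELS = ("ad_lib", "85pct", "75pct", "65pct", "55pct")
_DEFAULT_REPLICATES = (10, 5, 5, 5, 5)


@dataclass(frozen=True)
class SimParams:
    """Ground-truth generative parameters and noise model.

    Defaults reproduce the conditions of the reference duck trial:
    NE_m 549.54 and ME_m via K_m 0.8784 (kJ/(kg BW^0.75)/d), K_g 0.75,
    NE_g 10.41 kJ/g, K_p 0.60, K_f 0.926 (the reciprocal-convention
    value), diet GE 16.90 MJ/kg with 0.26% AIA and AME 13.5 MJ/kg,
    ad-libitum intake 113.47 g/d, a 171.12 g start weight with 14.02%
    protein and 16.85% fat, five feeding levels over a 14-day period with
    10/5/5/5/5 replicates.
    """

    nem_true: float = 549.54
    km_true: float = 0.8784
    kg_true: float = 0.75
    kp_true: float = 0.60
    kf_true: float = 1.0 / 1.08
    neg_true: float = 10.41
    ame_true: float = 13.5            # MJ/kg feed
    ge_diet: float = 16.90            # MJ/kg feed
    aia_diet: float = 0.26            # % of feed mass
    dm_digestibility: float = 0.755   # fraction of feed mass not excreted
    excreta_pools: int = 5            # replicate excreta pools assayed per group
    levels: tuple[float, ...] = _DEFAULT_LEVELS
    level_labels: tuple[str, ...] = _DEFAULT_LABELS
    replicates: tuple[int, ...] = _DEFAULT_REPLICATES
    n_initial: int = 10
    adfi_adlib: float = 113.47        # g/d
    start_bw: float = 171.12          # g
    start_protein_frac: float = 14.02  # % of BW
    start_fat_frac: float = 16.85      # % of BW
    ash_frac: float = 3.0              # % closure allowance
    days: int = 14
    mid_slaughter_day: int = 7         # days into the period; 0 disables
    mid_slaughter_replicates: int = 5
    noise_cv: float = 0.0
    hp_model: str = "linear_re"        # or "exponential"
    hp_log_slope: float = 0.00012      # b of the exponential mode
    replicate_offset: float = 15.0     # amplitude of e_r, kJ/(kg^0.75)/d
    fat_share_intercept: float = -285.0  # f0 of the affine fat partition
    fat_share_adlib: float = 0.62      # exponential-mode share at level 1.0
    fat_share_slope: float = 0.22      # exponential-mode share gradient
    seed: int | None = None

    @property
    def mem_true(self) -> float:
        return self.nem_true / self.km_true

    def validate(self) -> None:
        for name in ("km_true", "kg_true", "kp_true", "kf_true",
                     "dm_digestibility"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"SimParams.{name} must be in (0,1), got {v}")
        for name in ("nem_true", "neg_true", "ame_true", "ge_diet",
                     "aia_diet", "adfi_adlib", "start_bw"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"SimParams.{name} must be > 0")
        if self.ame_true >= self.ge_diet:
            raise ValidationError("ame_true must be below ge_diet")
        if not all(0 < lv <= 1 for lv in self.levels):
            raise ValidationError("levels must be fractions in (0, 1]")
        if any(b >= a for a, b in zip(self.levels, self.levels[1:])):
            raise ValidationError("levels must be strictly decreasing")
        if not (len(self.levels) == len(self.level_labels) == len(self.replicates)):
            raise ValidationError(
                "levels, level_labels and replicates must have equal length"
            )
        if self.hp_model not in ("linear_re", "exponential"):
            raise ValidationError(
                f"unknown hp_model {self.hp_model!r}; "
                "expected 'linear_re' or 'exponential'"
            )
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.noise_cv > 0 and self.seed is None:
            raise ValidationError("a seed is mandatory whenever noise_cv > 0")
        if self.days < 1:
            raise ValidationError("days must be >= 1")
        if self.kf_true == self.kp_true:
            raise ValidationError("kp_true and kf_true must differ")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimParams":
        """Load a flat-key scenario file."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(
                f"unknown scenario keys: {', '.join(sorted(unknown))}"
            )
        for key in ("levels", "level_labels", "replicates"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class _Trajectory:
    """Solved balance-period aggregate state of one replicate."""

    bw_final: float
    mbw_mid: float
    mei_pm: float       # kJ/(kg^0.75)/d
    re_total: float     # kJ
    rep_total: float    # kJ
    ref_total: float    # kJ


def _re_per_mbw(p: SimParams, mei_pm: float, offset: float) -> float:
    if p.hp_model == "linear_re":
        return p.kg_true * (mei_pm - p.mem_true) + offset
    hp = p.nem_true * 10.0 ** (p.hp_log_slope * mei_pm)
    return mei_pm - hp


def _solve_period(
    p: SimParams,
    start_bw: float,
    start_be: float,
    mei_per_day: float,
    days: int,
    offset: float,
) -> tuple[float, float, float]:
    """Fixed point for (bw_final, mbw_mid, mei_pm) of one period."""
    mei_total = mei_per_day * days
    bw_f = start_bw + 1.0
    for _ in range(200):
        mbw = ((start_bw + bw_f) / 2.0 / 1000.0) ** 0.75
        mei_pm = mei_total / (days * mbw)
        re_total = _re_per_mbw(p, mei_pm, offset) * days * mbw
        new_bw = start_bw + re_total / p.neg_true
        if new_bw <= 0 or start_be + re_total <= 0:
            raise SimulationError(
                "energy balance drives the carcass below zero energy; "
                "the parameter combination starves the birds out of scope"
            )
        if abs(new_bw - bw_f) < 1e-11:
            bw_f = new_bw
            break
        bw_f = new_bw
    mbw = ((start_bw + bw_f) / 2.0 / 1000.0) ** 0.75
    return bw_f, mbw, mei_total / (days * mbw)


def _partition(
    p: SimParams, level: float, mei_pm: float, re_pm: float
) -> tuple[float, float]:
    """Split per-mbw retained energy into (protein, fat) components."""
    if p.hp_model == "linear_re":
        # exact Boekholt plane: re_p/kp + re_f/kf = mei - b0 with b0 implied
        # by the affine fat partition anchor f0 = fat_share_intercept
        kp, kf, kg, mem = p.kp_true, p.kf_true, p.kg_true, p.mem_true
        f0 = p.fat_share_intercept
        p1 = kp * (kf - kg) / (kf - kp)
        f1 = kg - p1
        p0 = -kg * mem - f0
        b0 = -(p0 / kp + f0 / kf)
        # solve re_p + re_f = re_pm ; re_p/kp + re_f/kf = mei - b0
        rhs = mei_pm - b0
        re_p = kp * kf * (rhs - re_pm / kf) / (kf - kp)
        re_f = re_pm - re_p
        return re_p, re_f
    share = p.fat_share_adlib - p.fat_share_slope * (1.0 - level)
    share = min(max(share, 0.05), 0.95)
    return (1.0 - share) * re_pm, share * re_pm


def _replicate_offsets(p: SimParams, mei_pm: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Project the raw alternating pattern orthogonally to [1, MEI]."""
    if p.hp_model != "linear_re" or p.replicate_offset == 0:
        return np.zeros_like(u)
    M = np.column_stack([np.ones_like(mei_pm), mei_pm])
    coef, *_ = np.linalg.lstsq(M, u, rcond=None)
    e = u - M @ coef
    return p.replicate_offset * e


def simulate_trial(params: SimParams) -> TrialTables:
    """Generate one fully valid trial with known ground-truth parameters."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    start_protein = params.start_bw * params.start_protein_frac / 100.0
    start_fat = params.start_bw * params.start_fat_frac / 100.0
    consts = EnergyConstants()
    # internal consistency: baseline body energy is composition-implied so
    # that retained energy equals deposited protein+fat energy exactly
    start_be = start_protein * consts.e_protein + start_fat * consts.e_fat

    reps = [
        (label, level, r)
        for label, level, n in zip(
            params.level_labels, params.levels, params.replicates
        )
        for r in range(1, n + 1)
    ]
    mei_per_day = np.array(
        [lv * params.adfi_adlib * params.ame_true for _, lv, _ in reps]
    )

    # raw alternating within-level pattern for the replicate offsets
    u0 = np.empty(len(reps))
    i = 0
    for n in params.replicates:
        for r in range(n):
            u0[i] = 1.0 if r % 2 == 0 else -1.0
            i += 1

    # iterate offsets <-> trajectories to joint convergence: the offsets
    # must be orthogonal to [1, MEI] at the *final* MEI values
    e = np.zeros(len(reps))
    mei_pm = np.zeros(len(reps))
    for _ in range(80):
        for j, (_, _, _r) in enumerate(reps):
            _, _, mei_pm[j] = _solve_period(
                params, params.start_bw, start_be,
                mei_per_day[j], params.days, e[j],
            )
        e_new = _replicate_offsets(params, mei_pm, u0)
        if np.max(np.abs(e_new - e)) < 1e-12:
            e = e_new
            break
        e = e_new

    carcasses: list[CarcassRecord] = []
    intakes: list[IntakeRecord] = []

    def noisy(x: float) -> float:
        if params.noise_cv <= 0:
            return x
        sigma = np.sqrt(np.log1p(params.noise_cv**2))
        return float(x * np.exp(rng.normal(0.0, sigma) - sigma**2 / 2.0))

    def carcass(group: str, rep: str, age: float, bw: float, be: float,
                protein: float, fat: float) -> CarcassRecord:
        be_n = noisy(be)
        p_frac = noisy(protein / bw * 100.0)
        f_frac = noisy(fat / bw * 100.0)
        w_frac = 100.0 - params.ash_frac - p_frac - f_frac
        return CarcassRecord(
            group=group, replicate=rep, age_d=age, bw=bw,
            water_frac=w_frac, protein_frac=p_frac, fat_frac=f_frac,
            energy_density=be_n / bw, be=be_n,
        )

    # baseline slaughter group at the start of the period
    for r in range(1, params.n_initial + 1):
        carcasses.append(
            carcass("initial", f"r{r}", 7.0, params.start_bw, start_be,
                    start_protein, start_fat)
        )

    for j, (label, level, r) in enumerate(reps):
        bw_f, mbw, mpm = _solve_period(
            params, params.start_bw, start_be,
            mei_per_day[j], params.days, e[j],
        )
        re_pm = _re_per_mbw(params, mpm, e[j])
        re_total = re_pm * params.days * mbw
        rep_pm, ref_pm = _partition(params, level, mpm, re_pm)
        rep_total = rep_pm * params.days * mbw
        ref_total = ref_pm * params.days * mbw

        protein_f = start_protein + rep_total / consts.e_protein
        fat_f = start_fat + ref_total / consts.e_fat
        be_f = start_be + re_total

        intakes.append(
            IntakeRecord(label, f"r{r}", level * params.adfi_adlib,
                         float(params.days))
        )
        carcasses.append(
            carcass(label, f"r{r}", 7.0 + params.days, bw_f, be_f,
                    protein_f, fat_f)
        )

        # mid-period slaughter in the ad-libitum line (first replicates)
        if (
            label == params.level_labels[0]
            and 0 < params.mid_slaughter_day < params.days
            and r <= params.mid_slaughter_replicates
        ):
            d_mid = params.mid_slaughter_day
            bw_m, mbw_m, mpm_m = _solve_period(
                params, params.start_bw, start_be,
                mei_per_day[j], d_mid, e[j],
            )
            re_pm_m = _re_per_mbw(params, mpm_m, e[j])
            rep_pm_m, ref_pm_m = _partition(params, level, mpm_m, re_pm_m)
            scale_m = d_mid * mbw_m
            carcasses.append(
                carcass(label, f"r{r}", 7.0 + d_mid, bw_m,
                        start_be + re_pm_m * scale_m,
                        start_protein + rep_pm_m * scale_m / consts.e_protein,
                        start_fat + ref_pm_m * scale_m / consts.e_fat)
            )

    # excreta per group by marker and energy mass balance; the reported
    # group value is the mean of the replicate excreta pools assayed
    # separately (the metabolic experiment pools excreta by replicate)
    excreta = []
    mass_ratio = 1.0 - params.dm_digestibility  # excreta mass per feed mass
    n_pools = max(1, params.excreta_pools)
    for label in params.level_labels:
        ge_exc = (params.ge_diet - params.ame_true) / mass_ratio
        aia_exc = params.aia_diet / mass_ratio
        ge_mean = sum(noisy(ge_exc) for _ in range(n_pools)) / n_pools
        aia_mean = sum(noisy(aia_exc) for _ in range(n_pools)) / n_pools
        excreta.append(ExcretaAssay(label, ge_mean, aia_mean))

    diet = DietAssay(ge_diet=noisy(params.ge_diet),
                     aia_diet=noisy(params.aia_diet))
    design = tuple(zip(params.level_labels, params.levels))
    tables = TrialTables(diet, tuple(excreta), tuple(intakes),
                         tuple(carcasses), design)
    tables.validate()
    return tables


def recovery_study(
    params: SimParams,
    n_trials: int,
    mbw_convention: str = "midpoint",
) -> pd.DataFrame:
    """Parameter-recovery study: simulate + refit ``n_trials`` times.

    Trials use seeds ``seed .. seed + n_trials - 1``. Returns a frame with
    one row per parameter (nem, mem, kg, neg, kp, kf): the generative
    truth, the median estimate, and the median absolute relative error.
    Single-trial pipeline failures are counted, not fatal; the failure
    count is carried in the frame attribute ``attrs['failures']``.
    """
    if n_trials < 1:
        raise ValidationError(f"n_trials must be >= 1, got {n_trials}")
    params.validate()
    base_seed = params.seed if params.seed is not None else 0

    truths = {
        "nem": params.nem_true, "mem": params.mem_true,
        "kg": params.kg_true, "neg": params.neg_true,
        "kp": params.kp_true, "kf": params.kf_true,
    }
    estimates: dict[str, list[float]] = {k: [] for k in truths}
    failures = 0
    for t in range(n_trials):
        p_t = dataclasses.replace(params, seed=base_seed + t)
        failed = False
        try:
            tables = simulate_trial(p_t)
            ames = ame_table(tables)
            records = balance_table(tables, ames, EnergyConstants(),
                                    mbw_convention)
            m = fit_maintenance(records)
            g = fit_growth(list(tables.carcasses), m.kg)
            for k, v in (("nem", m.nem), ("mem", m.mem), ("kg", m.kg),
                         ("neg", g.neg)):
                estimates[k].append(v)
        except Exception:  # noqa: BLE001 - robustness of the study harness
            failures += 1
            continue
        try:
            # the partition fit can fail independently (near-collinear
            # RE_p/RE_f under noise); record it without discarding the
            # maintenance and growth estimates of the same trial
            e = fit_efficiency(records)
            estimates["kp"].append(e.kp)
            estimates["kf"].append(e.kf)
        except Exception:  # noqa: BLE001
            failed = True
        if failed:
            failures += 1

    rows = []
    for k, truth in truths.items():
        est = np.array(estimates[k])
        if est.size:
            med = float(np.median(est))
            med_err = float(np.median(np.abs(est - truth) / abs(truth)))
        else:
            med, med_err = float("nan"), float("nan")
        rows.append(
            {"parameter": k, "truth": truth, "median_estimate": med,
             "median_rel_error": med_err, "n_ok": int(est.size)}
        )
    out = pd.DataFrame(rows)
    out.attrs["failures"] = failures
    return out
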