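"""Factorial net-energy model for growing waterfowl.

The factorial method decomposes the net energy (NE) requirement into an
additive maintenance term, scaling with metabolic body weight, and a
growth term, scaling with daily gain:

    NE [kJ/d] = NE_m * BW^0.75 + NE_g * dW

The four parameter groups are estimated from a restricted-feeding
comparative-slaughter trial by three regressions:

* maintenance: the fasting-heat-production extrapolation of Lofgreen and
  Garrett — log10(HP) regressed on MEI, with NE_m the antilog of the
  intercept — together with the linear regression of RE on MEI, whose
  x-intercept is ME_m and whose slope is K_g (efficiency of ME use for
  energy retention); K_m = NE_m / ME_m;
* growth: the slope of whole-body energy on body weight across serial
  slaughters is NE_g (kJ per g of gain); ME_g = NE_g / K_g;
* partition: the Boekholt multiple regression
  MEI = b0 + b_p * RE_p + b_f * RE_f, whose coefficient reciprocals are
  the partial efficiencies K_p = 1/b_p and K_f = 1/b_f.

:class:`FactorialNEModel` wraps the full chain behind a statsmodels-style
interface: build the model from :class:`~netenergy.tables.TrialTables`
(or CSV files), call :meth:`~FactorialNEModel.fit`, and read estimates,
diagnostics and a summary table off the returned
:class:`FactorialNEResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference
from .ame import AmeResult, ame_table
from .balance import (
    EnergyBalanceRecord,
    EnergyConstants,
    balance_table,
    baseline_mean,
    performance,
)
from .exceptions import (
    DegreesOfFreedomError,
    RankError,
    ValidationError,
)
from .regression import FitResult, ols, x_intercept
from .tables import CarcassRecord, TrialTables, read_trial

LOG10 = 10.0


@dataclass(frozen=True)
class MaintenanceFit:
    """Maintenance parameters from the two MEI regressions.

    nem = 10^(intercept of log10 HP on MEI); mem = x-intercept of RE on
    MEI; kg = slope of RE on MEI; km = nem / mem. Units of nem/mem are
    kJ/(kg BW^0.75)/d.
    """

    log_intercept: float
    log_slope: float
    nem: float
    mem: float
    kg: float
    km: float
    log_fit: FitResult
    re_fit: FitResult


@dataclass(frozen=True)
class GrowthFit:
    """Growth parameters: neg (kJ/g gain) and meg = neg / kg."""

    neg: float
    meg: float
    fit: FitResult


@dataclass(frozen=True)
class EfficiencyFit:
    """Partial deposition efficiencies from the Boekholt regression."""

    b0: float
    b_p: float
    b_f: float
    kp: float
    kf: float
    fit: FitResult


@dataclass(frozen=True)
class RequirementEquation:
    """The assembled requirement predictor on the NE (and ME) scale."""

    nem: float
    neg: float
    exponent: float = 0.75
    mem: float | None = None
    meg: float | None = None

    def __post_init__(self) -> None:
        for name in ("nem", "neg", "exponent"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"RequirementEquation.{name} must be > 0")

    def __str__(self) -> str:
        s = f"NE = {self.nem:.2f} BW^{self.exponent:g} + {self.neg:.2f} dW"
        if self.mem is not None and self.meg is not None:
            s += f"   (ME scale: ME = {self.mem:.2f} BW^{self.exponent:g}"
            s += f" + {self.meg:.2f} dW)"
        return s


def fit_maintenance(
    records: list[EnergyBalanceRecord],
    weights: "np.typing.ArrayLike | None" = None,
) -> MaintenanceFit:
    """Maintenance parameters from per-replicate energy-balance records."""
    if len(records) < 3:
        raise DegreesOfFreedomError(
            f"need at least 3 balance records, got {len(records)}"
        )
    for r in records:
        if r.hp <= 0:
            raise ValidationError(
                f"record {r.group}/{r.replicate}: HP = {r.hp:.3f} <= 0, "
                "log10(HP) undefined"
            )
    mei = np.array([r.mei for r in records])
    if np.ptp(mei) == 0:
        raise RankError("all records share one MEI level; no spread to regress on")
    hp = np.array([r.hp for r in records])
    re = np.array([r.re for r in records])

    log_fit = ols(np.log10(hp), mei, weights)
    re_fit = ols(re, mei, weights)
    nem = LOG10 ** log_fit.intercept
    mem = x_intercept(re_fit)
    kg = re_fit.slope
    return MaintenanceFit(
        log_intercept=log_fit.intercept,
        log_slope=log_fit.slope,
        nem=nem, mem=mem, kg=kg, km=nem / mem,
        log_fit=log_fit, re_fit=re_fit,
    )


def fit_growth(
    carcasses: list[CarcassRecord],
    kg: float,
    weights: "np.typing.ArrayLike | None" = None,
) -> GrowthFit:
    """NE_g as the slope of whole-body energy on body weight."""
    if len(carcasses) < 3:
        raise DegreesOfFreedomError(
            f"need at least 3 carcass records, got {len(carcasses)}"
        )
    bw = np.array([c.bw for c in carcasses])
    be = np.array([c.be for c in carcasses])
    fit = ols(be, bw, weights)
    return GrowthFit(neg=fit.slope, meg=fit.slope / kg, fit=fit)


def fit_efficiency(
    records: list[EnergyBalanceRecord],
    weights: "np.typing.ArrayLike | None" = None,
) -> EfficiencyFit:
    """K_p and K_f as reciprocals of the Boekholt regression coefficients."""
    if len(records) < 4:
        raise DegreesOfFreedomError(
            f"need at least 4 balance records, got {len(records)}"
        )
    mei = np.array([r.mei for r in records])
    X = np.column_stack(
        [[r.re_p for r in records], [r.re_f for r in records]]
    )
    fit = ols(mei, X, weights)
    b0, b_p, b_f = fit.coefficients
    if b_p <= 0 or b_f <= 0:
        raise ValidationError(
            f"non-positive partition coefficients (b_p={b_p:.4f}, "
            f"b_f={b_f:.4f}); efficiencies undefined"
        )
    return EfficiencyFit(b0=b0, b_p=b_p, b_f=b_f, kp=1.0 / b_p, kf=1.0 / b_f,
                         fit=fit)


def build_equation(m: MaintenanceFit, g: GrowthFit) -> RequirementEquation:
    """Bundle maintenance and growth fits into the requirement predictor."""
    return RequirementEquation(
        nem=m.nem, neg=g.neg, exponent=0.75, mem=m.mem, meg=g.meg
    )


def predict_requirement(
    eq: RequirementEquation, bw_kg: float, dw: float, scale: str = "ne"
) -> float:
    """Daily energy requirement (kJ/d) for a bird of bw_kg gaining dw g/d."""
    if not bw_kg > 0:
        raise ValidationError(f"body weight must be positive, got {bw_kg}")
    if dw < 0:
        raise ValidationError(
            f"negative gain ({dw}) is outside the model's scope"
        )
    if scale == "ne":
        return eq.nem * bw_kg**eq.exponent + eq.neg * dw
    if scale == "me":
        if eq.mem is None or eq.meg is None:
            raise ValidationError("equation carries no ME-scale parameters")
        return eq.mem * bw_kg**eq.exponent + eq.meg * dw
    raise ValidationError(f"unknown scale {scale!r}; expected 'ne' or 'me'")


# ---------------------------------------------------------------------------
# Model / Results


class FactorialNEModel:
    """Factorial net-energy model built from trial tables.

    Parameters
    ----------
    tables
        Validated :class:`~netenergy.tables.TrialTables`.
    consts
        Energy equivalents and the metabolic-weight exponent.
    mbw_convention
        ``"midpoint"`` (default) or ``"daily-mean"``; how the mean
        metabolic body weight over the balance period is formed.
    weights
        ``None`` (unweighted, default) or ``"replicate-count"`` — weight
        each group-mean observation by its replicate count. Weighting only
        matters for degenerate one-record-per-group trials; with
        replicate-level records the unweighted fit is the published
        convention.
    """

    def __init__(
        self,
        tables: TrialTables,
        consts: EnergyConstants = EnergyConstants(),
        mbw_convention: str = "midpoint",
        weights: str | None = None,
    ) -> None:
        tables.validate()
        consts.validate()
        if weights not in (None, "replicate-count"):
            raise ValidationError(
                f"unknown weights mode {weights!r}; "
                "expected None or 'replicate-count'"
            )
        self.tables = tables
        self.consts = consts
        self.mbw_convention = mbw_convention
        self.weights = weights

    @classmethod
    def from_csv(
        cls, directory: str | Path, **kwargs: object
    ) -> "FactorialNEModel":
        """Build the model from a trial directory of CSV tables."""
        return cls(read_trial(directory), **kwargs)

    def fit(self) -> "FactorialNEResults":
        """Run the full estimation chain and return a results object."""
        ames = ame_table(self.tables)
        records = balance_table(
            self.tables, ames, self.consts, self.mbw_convention
        )
        w = None
        if self.weights == "replicate-count":
            counts: dict[str, int] = {}
            for rec in records:
                counts[rec.group] = counts.get(rec.group, 0) + 1
            w = np.array([1.0 / counts[rec.group] for rec in records])
            # each group contributes equally; within-group records share it

        maintenance = fit_maintenance(records, w)
        growth = fit_growth(list(self.tables.carcasses), maintenance.kg)
        efficiency = fit_efficiency(records, w)
        equation = build_equation(maintenance, growth)

        warns = []
        for rec in records:
            assert abs(rec.hp - (rec.mei - rec.re)) <= 1e-9 * max(1.0, abs(rec.mei))
        gap = max(abs(rec.re - (rec.re_p + rec.re_f)) for rec in records)
        if gap > 0.01 * max(abs(rec.re) for rec in records):
            warns.append(
                f"re_p + re_f deviates from re by up to {gap:.2f} "
                "kJ/(kg^0.75)/d; the gap is reported, not reconciled"
            )
        return FactorialNEResults(
            model=self, ames=ames, records=records,
            maintenance=maintenance, growth=growth, efficiency=efficiency,
            equation=equation, warnings_=tuple(warns),
        )


@dataclass(frozen=True)
class FactorialNEResults:
    """Fitted factorial model: estimates, diagnostics, prediction."""

    model: FactorialNEModel
    ames: list[AmeResult]
    records: list[EnergyBalanceRecord]
    maintenance: MaintenanceFit
    growth: GrowthFit
    efficiency: EfficiencyFit
    equation: RequirementEquation
    warnings_: tuple[str, ...] = ()

    @property
    def params(self) -> dict[str, float]:
        """Flat parameter bundle at full precision."""
        return {
            "nem": self.maintenance.nem,
            "mem": self.maintenance.mem,
            "km": self.maintenance.km,
            "kg": self.maintenance.kg,
            "neg": self.growth.neg,
            "meg": self.growth.meg,
            "kp": self.efficiency.kp,
            "kf": self.efficiency.kf,
        }

    def predict(self, bw_kg: float, dw: float, scale: str = "ne") -> float:
        """Daily requirement (kJ/d) at body weight bw_kg (kg), gain dw (g/d)."""
        return predict_requirement(self.equation, bw_kg, dw, scale)

    def ame_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": [a.group for a in self.ames],
                "ame_mj_per_kg": [a.ame for a in self.ames],
                "am_rate": [a.am_rate for a in self.ames],
                "flags": [";".join(a.flags) for a in self.ames],
            }
        )

    def balance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": [r.group for r in self.records],
                "replicate": [r.replicate for r in self.records],
                "mbw_kg075": [r.mbw for r in self.records],
                "mei": [r.mei for r in self.records],
                "re": [r.re for r in self.records],
                "hp": [r.hp for r in self.records],
                "re_p": [r.re_p for r in self.records],
                "re_f": [r.re_f for r in self.records],
            }
        )

    def performance_frame(self) -> pd.DataFrame:
        """Per-replicate growth performance (ADG, FCR)."""
        base = baseline_mean(self.model.tables)
        rows = []
        for intake in self.model.tables.intakes:
            target = base.age_d + intake.days
            finals = [
                c for c in self.model.tables.carcasses
                if c.group == intake.group and c.replicate == intake.replicate
                and abs(c.age_d - target) < 1e-9
            ]
            if not finals:
                continue
            adg, fcr = performance(intake, base.bw, finals[0].bw)
            rows.append(
                {"group": intake.group, "replicate": intake.replicate,
                 "adfi": intake.adfi, "adg": adg, "fcr": fcr}
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable summary table (display rounded to 2 decimals)."""
        m, g, e = self.maintenance, self.growth, self.efficiency
        lines = [
            "Factorial net-energy model",
            "=" * 62,
            f"records: {len(self.records)} balance replicates, "
            f"{len(self.model.tables.carcasses)} carcasses, "
            f"{len(self.model.tables.design)} feeding levels",
            "",
            "Maintenance (kJ/(kg BW^0.75)/d)",
            f"  log10(HP) = {m.log_intercept:.4f} + {m.log_slope:.6f} x MEI"
            f"   (R2={m.log_fit.r2:.3f}, RMSE={m.log_fit.rmse:.3f}, n={m.log_fit.n})",
            f"  RE = {m.re_fit.slope:.4f} x MEI {m.re_fit.intercept:+.2f}"
            f"   (R2={m.re_fit.r2:.3f}, RMSE={m.re_fit.rmse:.3f}, n={m.re_fit.n})",
            f"  NE_m = {m.nem:.2f}   ME_m = {m.mem:.2f}   "
            f"K_m = {m.km:.2f}   K_g = {m.kg:.2f}",
            "",
            "Growth (kJ/g gain)",
            f"  BE = {g.fit.intercept:+.2f} + {g.fit.slope:.4f} x BW"
            f"   (R2={g.fit.r2:.3f}, RMSE={g.fit.rmse:.3f}, n={g.fit.n})",
            f"  NE_g = {g.neg:.2f}   ME_g = {g.meg:.2f}",
            "",
            "Deposition efficiencies",
            f"  MEI = {e.b0:.2f} + {e.b_p:.4f} x RE_p + {e.b_f:.4f} x RE_f"
            f"   (R2={e.fit.r2:.3f}, RMSE={e.fit.rmse:.3f}, n={e.fit.n})",
            f"  K_p = {e.kp:.2f}   K_f = {e.kf:.2f}",
            "",
            "Requirement equation",
            f"  {self.equation}",
        ]
        for wmsg in self.warnings_:
            lines += ["", f"WARNING: {wmsg}"]
        return "\n".join(lines)

    def to_kv(self) -> str:
        """Machine-readable flat key-value parameter block, full precision."""
        return "\n".join(f"{k}={v!r}" for k, v in self.params.items()) + "\n"


# ---------------------------------------------------------------------------
# Desk reproduction of the published reference values


def reproduce_reference() -> pd.DataFrame:
    """Recompute the published duck-trial values from printed inputs only.

    Each derived quantity is recomputed by its defining arithmetic from the
    published inputs (assay values, group means, regression coefficients):
    the antilog of the log-HP intercept, the x-intercept of the RE-MEI
    line, efficiency ratios and reciprocals, the growth slope refitted to
    the three serial-slaughter (BW, BE) means, heat production from the
    bookkeeping identity, and marker-formula AME per group. Returns a
    side-by-side frame of computed vs published values with deviations and
    flags on the rows whose published values are internally inconsistent.
    """
    rows: list[dict[str, object]] = []

    def add(name: str, computed: float, published: float | None,
            note: str = "") -> None:
        dev = None if published is None else computed - published
        rows.append(
            {"quantity": name, "computed": computed, "published": published,
             "deviation": dev, "note": note}
        )

    pub = reference.PUBLISHED_PARAMS

    nem = LOG10 ** reference.LOG_HP_VS_MEI["intercept"]
    re_fit = FitResult(
        coefficients=(reference.RE_VS_MEI["intercept"],
                      reference.RE_VS_MEI["slope"]),
        r2=reference.RE_VS_MEI["r2"], rmse=reference.RE_VS_MEI["rmse"],
        n=15, cond=float("nan"),
    )
    mem = x_intercept(re_fit)
    kg = reference.RE_VS_MEI["slope"]
    add("nem", nem, pub["nem"], "antilog of published log10HP intercept")
    add("mem", mem, pub["mem"], "x-intercept of published RE-MEI line")
    add("km", nem / mem, pub["km"])
    add("kg", kg, pub["kg"], "published RE-MEI slope, taken as input")

    bw = [a["bw"] for a in reference.AGE_MEANS]
    be = [a["be"] for a in reference.AGE_MEANS]
    growth = ols(be, bw)
    add("neg", growth.slope, pub["neg"],
        "refit to the three serial-slaughter (BW, BE) means")
    add("meg", pub["neg"] / kg, pub["meg"], "published NE_g / K_g")

    add("kp", 1.0 / reference.MEI_VS_REP_REF["b_p"], pub["kp"],
        "reciprocal of published RE_p coefficient")
    add("kf", 1.0 / reference.MEI_VS_REP_REF["b_f"], pub["kf"],
        reference.FLAGS["params/kf"])

    for group, row in reference.BALANCE.items():
        note = ""
        if f"balance/{group}" in reference.FLAGS:
            note = reference.FLAGS[f"balance/{group}"]
        add(f"hp_{group}", row["mei"] - row["re"], row["hp"], note)

    for exc in reference.EXCRETA:
        res_ame = (
            reference.DIET.ge_diet
            - exc.ge_excreta * reference.DIET.aia_diet / exc.aia_excreta
        )
        published_ame = {
            "ad_lib": 13.43, "85pct": 13.51, "75pct": 13.60,
            "65pct": 13.72, "55pct": 13.77,
        }[exc.group]
        add(f"ame_{exc.group}", res_ame, published_ame,
            "marker formula on published two-decimal assays")

    final = reference.AGE_MEANS[2]
    add("bwe_21d", final["be"] / final["bw"], 9.85,
        "body energy density at 21 d, BE/BW")

    return pd.DataFrame(rows)
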