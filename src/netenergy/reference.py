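"""Bundled reference dataset: a published restricted-feeding trial with
2-to-3-week-old Cherry Valley ducks.

The trial fed five groups at graded levels (ad libitum and 85%, 75%, 65%,
55% of ad libitum intake) over a 14-day balance period (age 7 d to 21 d),
with serial slaughters at 7, 14 and 21 d. Only group means were published,
so the dataset is shipped as a degenerate one-replicate-per-group trial:
useful for desk-checking every arithmetic step of the pipeline, but not for
re-estimating replicate-level regression coefficients.

Two published inconsistencies are carried as machine-readable flags rather
than silently repaired:

* the 55% group's heat production does not satisfy HP = MEI - RE
  (1498.00 - 622.82 = 875.18, not the published 835.19); the pipeline
  recomputes HP from the identity and flags the row;
* the published fat-deposition efficiency K_f = 0.96 is not the reciprocal
  of the published regression coefficient 1.08 (1/1.08 = 0.926); the
  reciprocal convention is retained and the row flagged.
"""

from __future__ import annotations

from types import MappingProxyType

from .tables import (
    CarcassRecord,
    DietAssay,
    ExcretaAssay,
    IntakeRecord,
    TrialTables,
)

#: Ordered feeding-level labels with nominal restriction fractions.
DESIGN = (
    ("ad_lib", 1.00),
    ("85pct", 0.85),
    ("75pct", 0.75),
    ("65pct", 0.65),
    ("55pct", 0.55),
)

GROUPS = tuple(g for g, _ in DESIGN)

#: Feed assay (identical for all groups): GE MJ/kg air-dry, AIA % of mass.
DIET = DietAssay(ge_diet=16.90, aia_diet=0.26)

#: Per-group excreta assays: GE MJ/kg, AIA % of mass.
EXCRETA = (
    ExcretaAssay("ad_lib", 14.10, 1.06),
    ExcretaAssay("85pct", 13.85, 1.06),
    ExcretaAssay("75pct", 13.93, 1.10),
    ExcretaAssay("65pct", 13.51, 1.11),
    ExcretaAssay("55pct", 13.39, 1.12),
)

#: Published group-mean performance: ADFI g/d, ADG g/d, FCR.
PERFORMANCE = MappingProxyType({
    "ad_lib": {"adfi": 113.47, "adg": 69.31, "fcr": 1.64},
    "85pct": {"adfi": 95.67, "adg": 58.04, "fcr": 1.65},
    "75pct": {"adfi": 83.76, "adg": 49.91, "fcr": 1.68},
    "65pct": {"adfi": 72.61, "adg": 42.70, "fcr": 1.70},
    "55pct": {"adfi": 61.51, "adg": 35.83, "fcr": 1.72},
})

#: Published group-mean energy balance, kJ/(kg BW^0.75)/d.
BALANCE = MappingProxyType({
    "ad_lib": {"mei": 1934.25, "re": 984.99, "hp": 949.26},
    "85pct": {"mei": 1805.63, "re": 892.64, "hp": 913.00},
    "75pct": {"mei": 1720.48, "re": 822.22, "hp": 898.26},
    "65pct": {"mei": 1625.33, "re": 741.27, "hp": 884.06},
    "55pct": {"mei": 1498.00, "re": 622.82, "hp": 835.19},
})

#: Published group-mean retained energy as fat/protein, kJ/(kg BW^0.75)/d.
RE_PARTITION = MappingProxyType({
    "ad_lib": {"re_f": 621.85, "re_p": 381.98},
    "85pct": {"re_f": 544.29, "re_p": 359.81},
    "75pct": {"re_f": 468.94, "re_p": 346.72},
    "65pct": {"re_f": 402.09, "re_p": 332.19},
    "55pct": {"re_f": 337.92, "re_p": 310.43},
})

#: Published group-mean 21-d body composition (water/protein/fat %, kJ/g).
COMPOSITION_21D = MappingProxyType({
    "ad_lib": {"water": 63.97, "protein": 16.50, "fat": 15.64, "energy": 9.85},
    "85pct": {"water": 64.47, "protein": 16.75, "fat": 14.79, "energy": 9.63},
    "75pct": {"water": 64.59, "protein": 17.19, "fat": 13.73, "energy": 9.48},
    "65pct": {"water": 65.18, "protein": 17.61, "fat": 12.78, "energy": 9.21},
    "55pct": {"water": 65.58, "protein": 17.84, "fat": 11.89, "energy": 9.00},
})

#: Serial-slaughter age-group means (ad-libitum line): BW g, BE kJ, %s.
AGE_MEANS = (
    {"age_d": 7.0, "bw": 171.12, "be": 1196.28, "water": 72.55,
     "protein": 14.02, "fat": 16.85, "energy": 6.99},
    {"age_d": 14.0, "bw": 572.70, "be": 4815.71, "water": 68.01,
     "protein": 14.64, "fat": 15.64, "energy": 8.41},
    {"age_d": 21.0, "bw": 1143.88, "be": 11264.76, "water": 63.97,
     "protein": 16.50, "fat": 13.68, "energy": 9.83},
)

#: Published regression of log10 heat production on MEI
#: (kJ/(kg BW^0.75)/d scale): intercept, slope, R^2, RMSE.
LOG_HP_VS_MEI = MappingProxyType(
    {"intercept": 2.74, "slope": 0.00012, "r2": 0.939, "rmse": 0.005}
)

#: Published regression of retained energy on MEI: RE = 0.75 MEI - 469.19.
RE_VS_MEI = MappingProxyType(
    {"intercept": -469.19, "slope": 0.75, "r2": 0.993, "rmse": 9.605}
)

#: Published regression of whole-body energy on body weight (n = 15
#: replicate-level observations, unavailable): BE = -793.02 + 10.41 BW.
BE_VS_BW = MappingProxyType(
    {"intercept": -793.02, "slope": 10.41, "r2": 0.996, "rmse": 276.822}
)

#: Published two-predictor regression MEI = 149.56 + 1.67 REp + 1.08 REf.
MEI_VS_REP_REF = MappingProxyType(
    {"intercept": 149.56, "b_p": 1.67, "b_f": 1.08, "r2": 0.991, "rmse": 3.623}
)

#: Published parameter values as printed (for side-by-side comparison).
PUBLISHED_PARAMS = MappingProxyType({
    "nem": 549.54, "mem": 625.59, "km": 0.88, "kg": 0.75,
    "neg": 10.41, "meg": 13.88, "kp": 0.60, "kf": 0.96,
})

#: Machine-readable flags for rows whose published values are internally
#: inconsistent; keys are (table, row) style identifiers.
FLAGS = MappingProxyType({
    "balance/55pct": (
        "published HP 835.19 violates HP = MEI - RE "
        "(1498.00 - 622.82 = 875.18); HP recomputed from the identity"
    ),
    "params/kf": (
        "published K_f 0.96 is not the reciprocal of the published "
        "coefficient 1.08 (1/1.08 = 0.926); reciprocal convention retained"
    ),
})

BALANCE_PERIOD_D = 14.0


def reference_trial() -> TrialTables:
    """The published group means as a degenerate one-replicate-per-group trial.

    Group 21-d body weights for the restricted groups (only the ad-libitum
    group's 21-d mean was published) are reconstructed as
    ``BW(7 d) + ADG x 14 d`` from the published average daily gains, and
    their body energies as BW x published 21-d energy density.
    """
    intakes = tuple(
        IntakeRecord(g, "mean", PERFORMANCE[g]["adfi"], BALANCE_PERIOD_D)
        for g in GROUPS
    )

    carcasses = [
        CarcassRecord(
            group="initial", replicate="mean", age_d=7.0,
            bw=AGE_MEANS[0]["bw"], water_frac=AGE_MEANS[0]["water"],
            protein_frac=AGE_MEANS[0]["protein"], fat_frac=AGE_MEANS[0]["fat"],
            energy_density=AGE_MEANS[0]["energy"], be=AGE_MEANS[0]["be"],
        ),
        CarcassRecord(
            group="ad_lib", replicate="mean", age_d=14.0,
            bw=AGE_MEANS[1]["bw"], water_frac=AGE_MEANS[1]["water"],
            protein_frac=AGE_MEANS[1]["protein"], fat_frac=AGE_MEANS[1]["fat"],
            energy_density=AGE_MEANS[1]["energy"], be=AGE_MEANS[1]["be"],
        ),
    ]
    bw0 = AGE_MEANS[0]["bw"]
    for g in GROUPS:
        comp = COMPOSITION_21D[g]
        if g == "ad_lib":
            bw, be = AGE_MEANS[2]["bw"], AGE_MEANS[2]["be"]
        else:
            bw = bw0 + PERFORMANCE[g]["adg"] * BALANCE_PERIOD_D
            be = None  # computed as bw * energy_density
        carcasses.append(
            CarcassRecord(
                group=g, replicate="mean", age_d=21.0, bw=bw,
                water_frac=comp["water"], protein_frac=comp["protein"],
                fat_frac=comp["fat"], energy_density=comp["energy"], be=be,
            )
        )

    tables = TrialTables(DIET, EXCRETA, intakes, tuple(carcasses), DESIGN)
    tables.validate()
    return tables
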