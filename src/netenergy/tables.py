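"""Typed data model for a restricted-feeding comparative-slaughter trial.

A trial is described by four tables:

* a single diet assay (gross energy and acid-insoluble-ash marker content
  of the feed),
* one excreta assay per feeding-level group (gross energy and marker
  content of the dried excreta),
* an intake log per replicate (average daily feed intake over the balance
  period),
* carcass records per slaughter event (body weight, water/protein/fat
  fractions, carcass energy density, whole-body energy).

Units are fixed per column: MJ/kg for assay energies (numerically equal to
kJ/g), kJ for whole-body energies, g for masses, days for periods. No unit
auto-detection is attempted — silent unit mixing is the chief failure mode
of energy bookkeeping.

The reserved group label ``"initial"`` marks the baseline slaughter group
(killed at the start of the balance period); it is exempt from intake
pairing and from membership in the feeding-level design.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .exceptions import SchemaError, UnknownGroupError, ValidationError

INITIAL_GROUP = "initial"

#: Relative tolerance for the redundancy check be ~= bw * energy_density.
BE_CONSISTENCY_RTOL = 0.01

#: Upper bound (%) for the water+protein+fat composition closure.
COMPOSITION_CLOSURE_MAX = 105.0


@dataclass(frozen=True)
class DietAssay:
    """Feed assay: gross energy (MJ/kg air-dry) and AIA marker (% of mass)."""

    ge_diet: float
    aia_diet: float

    def validate(self) -> None:
        if not self.ge_diet > 0:
            raise ValidationError(f"diet: ge_diet must be > 0, got {self.ge_diet}")
        if not 0 < self.aia_diet < 100:
            raise ValidationError(
                f"diet: aia_diet must be in (0, 100), got {self.aia_diet}"
            )


@dataclass(frozen=True)
class ExcretaAssay:
    """Per-group excreta assay: gross energy (MJ/kg) and AIA (% of mass)."""

    group: str
    ge_excreta: float
    aia_excreta: float

    def validate(self, diet: DietAssay | None = None) -> None:
        if not self.ge_excreta >= 0:
            raise ValidationError(
                f"excreta[{self.group}]: ge_excreta must be >= 0, got {self.ge_excreta}"
            )
        if not self.aia_excreta > 0:
            raise ValidationError(
                f"excreta[{self.group}]: aia_excreta must be > 0, got {self.aia_excreta}"
            )
        if diet is not None and self.aia_excreta < diet.aia_diet:
            # the indigestible marker concentrates in excreta whenever any
            # of the feed mass is digested
            raise ValidationError(
                f"excreta[{self.group}]: aia_excreta ({self.aia_excreta}) below "
                f"aia_diet ({diet.aia_diet}); marker cannot dilute"
            )


@dataclass(frozen=True)
class IntakeRecord:
    """Per-replicate average daily feed intake (g/d) over a balance period."""

    group: str
    replicate: str
    adfi: float
    days: float

    def validate(self) -> None:
        if not self.adfi >= 0:
            raise ValidationError(
                f"intake[{self.group}/{self.replicate}]: adfi must be >= 0, "
                f"got {self.adfi}"
            )
        if not self.days > 0:
            raise ValidationError(
                f"intake[{self.group}/{self.replicate}]: days must be > 0, "
                f"got {self.days}"
            )


@dataclass(frozen=True)
class CarcassRecord:
    """One slaughter event: body weight, composition, and body energy.

    ``be`` (whole-body energy, kJ) is redundant with
    ``bw * energy_density``; when both are supplied they must agree within
    1%, and when ``be`` is omitted it is computed from the product.
    """

    group: str
    replicate: str
    age_d: float
    bw: float
    water_frac: float
    protein_frac: float
    fat_frac: float
    energy_density: float
    be: float | None = None

    def __post_init__(self) -> None:
        if self.be is None:
            object.__setattr__(self, "be", self.bw * self.energy_density)

    def validate(self) -> None:
        tag = f"carcass[{self.group}/{self.replicate}@{self.age_d}d]"
        if not self.bw > 0:
            raise ValidationError(f"{tag}: bw must be > 0, got {self.bw}")
        for name in ("water_frac", "protein_frac", "fat_frac"):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise ValidationError(f"{tag}: {name} must be in (0, 100), got {v}")
        total = self.water_frac + self.protein_frac + self.fat_frac
        # water, protein and fat are assayed by different wet-chemistry
        # methods and can overshoot closure slightly on real carcasses
        # (the bundled 7-d baseline sums to 103.42%); tolerate up to 105%
        if total >= COMPOSITION_CLOSURE_MAX:
            raise ValidationError(
                f"{tag}: water+protein+fat sums to {total:.2f}%, "
                f"above the closure tolerance {COMPOSITION_CLOSURE_MAX}%"
            )
        if total >= 100:
            warnings.warn(
                f"{tag}: water+protein+fat sums to {total:.2f}% (> 100%); "
                "assay fractions overshoot closure",
                stacklevel=2,
            )
        if not self.energy_density > 0:
            raise ValidationError(
                f"{tag}: energy_density must be > 0, got {self.energy_density}"
            )
        implied = self.bw * self.energy_density
        if abs(self.be - implied) > BE_CONSISTENCY_RTOL * implied:
            raise ValidationError(
                f"{tag}: be ({self.be}) disagrees with bw*energy_density "
                f"({implied:.2f}) by more than {BE_CONSISTENCY_RTOL:.0%}"
            )

    @property
    def protein_mass(self) -> float:
        """Carcass protein mass, g."""
        return self.bw * self.protein_frac / 100.0

    @property
    def fat_mass(self) -> float:
        """Carcass fat mass, g."""
        return self.bw * self.fat_frac / 100.0


@dataclass(frozen=True)
class TrialTables:
    """The four validated tables of one trial plus the feeding-level design.

    ``design`` maps ordered feeding-level labels to their nominal
    restriction fractions (1.0 for ad libitum); ``None`` for a fraction
    means the nominal level is unknown (e.g. when read back from files).
    """

    diet: DietAssay
    excreta: tuple[ExcretaAssay, ...]
    intakes: tuple[IntakeRecord, ...]
    carcasses: tuple[CarcassRecord, ...]
    design: tuple[tuple[str, float | None], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "excreta", tuple(self.excreta))
        object.__setattr__(self, "intakes", tuple(self.intakes))
        object.__setattr__(self, "carcasses", tuple(self.carcasses))
        object.__setattr__(
            self, "design", tuple((g, f) for g, f in self.design)
        )

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.design)

    def validate(self) -> None:
        self.diet.validate()
        if len(self.design) < 2:
            raise ValidationError(
                "design must contain at least two feeding levels "
                "(the regressions need spread in MEI)"
            )
        known = set(self.groups)
        for exc in self.excreta:
            exc.validate(self.diet)
            if exc.group not in known:
                raise UnknownGroupError(
                    f"excreta references unknown group {exc.group!r}"
                )
        for rec in self.intakes:
            rec.validate()
            if rec.group not in known:
                raise UnknownGroupError(
                    f"intake references unknown group {rec.group!r}"
                )
        if not self.carcasses:
            raise ValidationError("carcass table is empty")
        for car in self.carcasses:
            car.validate()
            if car.group not in known and car.group != INITIAL_GROUP:
                raise UnknownGroupError(
                    f"carcass references unknown group {car.group!r}"
                )

    def excreta_for(self, group: str) -> ExcretaAssay:
        for exc in self.excreta:
            if exc.group == group:
                return exc
        raise UnknownGroupError(f"no excreta assay for group {group!r}")

    def initial_carcasses(self) -> tuple[CarcassRecord, ...]:
        return tuple(c for c in self.carcasses if c.group == INITIAL_GROUP)


# ---------------------------------------------------------------------------
# CSV I/O
#
# Dialect: comma-separated, header row, "." decimal, no thousands
# separators, UTF-8. File names within a trial directory are fixed.

_FILES = ("diet.csv", "excreta.csv", "intake.csv", "carcass.csv", "design.csv")

_REQUIRED = {
    "diet.csv": ["ge_diet", "aia_diet"],
    "excreta.csv": ["group", "ge_excreta", "aia_excreta"],
    "intake.csv": ["group", "replicate", "adfi", "days"],
    "carcass.csv": [
        "group", "replicate", "age_d", "bw",
        "water_frac", "protein_frac", "fat_frac", "energy_density",
    ],
    "design.csv": ["group", "level"],
}


def _read_csv(path: Path, name: str) -> pd.DataFrame:
    if not path.is_file():
        raise SchemaError(f"missing input file: {path}")
    try:
        df = pd.read_csv(
            path,
            dtype={"group": str, "replicate": str},
            float_precision="round_trip",
        )
    except Exception as err:  # noqa: BLE001 - reported as a schema problem
        raise SchemaError(f"{path}: cannot parse as CSV ({err})") from err
    for col in _REQUIRED[name]:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def read_trial(
    directory: str | Path | None = None,
    *,
    diet: str | Path | None = None,
    excreta: str | Path | None = None,
    intake: str | Path | None = None,
    carcass: str | Path | None = None,
    design: str | Path | None = None,
) -> TrialTables:
    """Read and validate the four trial tables from a directory or paths.

    Either ``directory`` (containing diet.csv, excreta.csv, intake.csv,
    carcass.csv and optionally design.csv) or the four per-table paths must
    be given. When no design file exists the design is inferred from the
    order of groups in the excreta table, with unknown nominal levels.
    """
    if directory is not None:
        directory = Path(directory)
        paths = {name: directory / name for name in _FILES}
    else:
        given = {
            "diet.csv": diet, "excreta.csv": excreta,
            "intake.csv": intake, "carcass.csv": carcass, "design.csv": design,
        }
        missing = [k for k, v in given.items() if v is None and k != "design.csv"]
        if missing:
            raise SchemaError(f"missing table paths: {', '.join(missing)}")
        paths = {k: Path(v) if v is not None else None for k, v in given.items()}
    return _read_tables(paths)


def _read_tables(paths: Mapping[str, Path | None]) -> TrialTables:
    diet_df = _read_csv(paths["diet.csv"], "diet.csv")
    if len(diet_df) != 1:
        raise SchemaError(f"{paths['diet.csv']}: expected exactly one row")
    diet_assay = DietAssay(
        ge_diet=float(diet_df.at[0, "ge_diet"]),
        aia_diet=float(diet_df.at[0, "aia_diet"]),
    )

    exc_df = _read_csv(paths["excreta.csv"], "excreta.csv")
    excreta = tuple(
        ExcretaAssay(str(r.group), float(r.ge_excreta), float(r.aia_excreta))
        for r in exc_df.itertuples()
    )

    design_path = paths.get("design.csv")
    if design_path is not None and design_path.is_file():
        design_df = _read_csv(design_path, "design.csv")
        design = tuple(
            (str(r.group), None if pd.isna(r.level) else float(r.level))
            for r in design_df.itertuples()
        )
    else:
        design = tuple((e.group, None) for e in excreta)

    int_df = _read_csv(paths["intake.csv"], "intake.csv")
    intakes = tuple(
        IntakeRecord(str(r.group), str(r.replicate), float(r.adfi), float(r.days))
        for r in int_df.itertuples()
    )

    car_df = _read_csv(paths["carcass.csv"], "carcass.csv")
    has_be = "be" in car_df.columns
    carcasses = tuple(
        CarcassRecord(
            group=str(r.group),
            replicate=str(r.replicate),
            age_d=float(r.age_d),
            bw=float(r.bw),
            water_frac=float(r.water_frac),
            protein_frac=float(r.protein_frac),
            fat_frac=float(r.fat_frac),
            energy_density=float(r.energy_density),
            be=(float(r.be) if has_be and not pd.isna(r.be) else None),
        )
        for r in car_df.itertuples()
    )

    tables = TrialTables(diet_assay, excreta, intakes, carcasses, design)
    tables.validate()
    return tables


def write_trial(tables: TrialTables, directory: str | Path) -> None:
    """Write a validated trial to a directory; round-trips at full precision."""
    tables.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    # shortest-round-trip float repr so read_trial(write_trial(t)) == t
    fmt = {"float_format": lambda v: repr(float(v)), "index": False}

    pd.DataFrame([dataclasses.asdict(tables.diet)]).to_csv(
        directory / "diet.csv", **fmt
    )
    pd.DataFrame(
        [{"group": g, "level": lv} for g, lv in tables.design]
    ).to_csv(directory / "design.csv", **fmt)
    pd.DataFrame([dataclasses.asdict(e) for e in tables.excreta]).to_csv(
        directory / "excreta.csv", **fmt
    )
    pd.DataFrame([dataclasses.asdict(i) for i in tables.intakes]).to_csv(
        directory / "intake.csv", **fmt
    )
    pd.DataFrame([dataclasses.asdict(c) for c in tables.carcasses]).to_csv(
        directory / "carcass.csv", **fmt
    )
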