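"""Apparent metabolizable energy by the acid-insoluble-ash marker method.

AIA is a naturally occurring indigestible mineral fraction of the feed.
Because the marker is conserved through the gut, the feed-to-excreta mass
ratio equals the inverse ratio of the marker concentrations, so the energy
excreted per kg of feed is ``GE_excreta * AIA_diet / AIA_excreta`` and

    AME = GE_diet - GE_excreta * (AIA_diet / AIA_excreta)     [MJ/kg feed]

The apparent metabolizability AM = AME / GE_diet is stored as a fraction
and rendered as a percentage only in reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .exceptions import ValidationError
from .tables import DietAssay, ExcretaAssay, TrialTables


@dataclass(frozen=True)
class AmeResult:
    """Per-group apparent metabolizable energy (MJ/kg) and metabolizability."""

    group: str
    ame: float
    am_rate: float
    flags: tuple[str, ...] = ()


def compute_ame(diet: DietAssay, excreta: ExcretaAssay) -> AmeResult:
    """AME of the diet for one group from paired feed and excreta assays.

    A negative computed AME (possible under heavy assay noise) is returned
    flagged with a warning rather than raised, so that noisy simulated
    assays do not abort a run.
    """
    if excreta.aia_excreta <= 0:
        raise ValidationError(
            f"excreta[{excreta.group}]: aia_excreta must be positive for the "
            f"marker ratio, got {excreta.aia_excreta}"
        )
    ame = diet.ge_diet - excreta.ge_excreta * (diet.aia_diet / excreta.aia_excreta)
    flags: tuple[str, ...] = ()
    if ame < 0:
        warnings.warn(
            f"group {excreta.group!r}: computed AME is negative ({ame:.3f} "
            "MJ/kg); feed and excreta assays are mutually inconsistent",
            stacklevel=2,
        )
        flags = ("negative_ame",)
    return AmeResult(group=excreta.group, ame=ame, am_rate=ame / diet.ge_diet,
                     flags=flags)


def ame_table(tables: TrialTables) -> list[AmeResult]:
    """One AmeResult per design group, in design order."""
    return [compute_ame(tables.diet, tables.excreta_for(g)) for g in tables.groups]
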