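"""Bioavailability / drug-likeness screening and cross-herb deduplication."""

from __future__ import annotations

import warnings
from collections.abc import Iterable
from dataclasses import dataclass

from .core import CompoundRecord, HerbSummary, TargetMap


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for the activity screen.

    Defaults keep compounds with ob >= 30 (%) and dl >= 0.18; set
    ``inclusive=False`` for strict inequalities.
    """

    ob_min: float = 30.0
    dl_min: float = 0.18
    inclusive: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.ob_min <= 100.0:
            raise ValueError(f"ob_min out of [0, 100]: {self.ob_min}")
        if not 0.0 <= self.dl_min <= 1.0:
            raise ValueError(f"dl_min out of [0, 1]: {self.dl_min}")

    def passes(self, record: CompoundRecord) -> bool:
        if self.inclusive:
            return record.ob >= self.ob_min and record.dl >= self.dl_min
        return record.ob > self.ob_min and record.dl > self.dl_min


@dataclass(frozen=True)
class UniqueCompound:
    """One compound after cross-herb deduplication; herb memberships merged."""

    mol_id: str
    name: str
    ob: float
    dl: float
    herbs: tuple[str, ...]
    n_targets: int | None = None


def screen_compounds(
    records: Iterable[CompoundRecord], config: ScreenConfig | None = None
) -> list[CompoundRecord]:
    """Return exactly the records passing the screen, input order preserved."""
    config = config or ScreenConfig()
    return [r for r in records if config.passes(r)]


def dedupe_compounds(
    records: Iterable[CompoundRecord],
) -> tuple[list[UniqueCompound], int]:
    """Collapse herb-level listings to one representative per mol_id.

    Every listing of an already-seen mol_id counts as one removed
    duplicate, so ``len(unique) + n_removed == len(records)``.  Herb
    memberships are merged in first-appearance order.  If later listings
    disagree on ob/dl, the first occurrence wins with a warning.
    """
    order: list[str] = []
    first: dict[str, CompoundRecord] = {}
    herbs: dict[str, list[str]] = {}
    n_records = 0
    for rec in records:
        n_records += 1
        if rec.mol_id not in first:
            order.append(rec.mol_id)
            first[rec.mol_id] = rec
            herbs[rec.mol_id] = [rec.herb]
        else:
            ref = first[rec.mol_id]
            if (rec.ob, rec.dl) != (ref.ob, ref.dl):
                warnings.warn(
                    f"conflicting ob/dl for {rec.mol_id}: "
                    f"({rec.ob}, {rec.dl}) vs first ({ref.ob}, {ref.dl}); "
                    "keeping first",
                    stacklevel=2,
                )
            if rec.herb not in herbs[rec.mol_id]:
                herbs[rec.mol_id].append(rec.herb)
    unique = [
        UniqueCompound(
            mol_id=m,
            name=first[m].name,
            ob=first[m].ob,
            dl=first[m].dl,
            herbs=tuple(herbs[m]),
            n_targets=first[m].n_targets,
        )
        for m in order
    ]
    return unique, n_records - len(unique)


def summarize_by_herb(
    all_records: Iterable[CompoundRecord],
    screened_records: Iterable[CompoundRecord],
    target_map: TargetMap | None = None,
) -> list[HerbSummary]:
    """Per-herb counts of compounds, screen survivors, and target-union size.

    Herbs with zero survivors are reported with explicit zeros, never
    dropped.  Herb order follows first appearance in ``all_records``.
    """
    all_records = list(all_records)
    screened_records = list(screened_records)
    herb_order: list[str] = []
    compounds: dict[str, set[str]] = {}
    for rec in all_records:
        if rec.herb not in compounds:
            herb_order.append(rec.herb)
            compounds[rec.herb] = set()
        compounds[rec.herb].add(rec.mol_id)
    bioactive: dict[str, set[str]] = {h: set() for h in herb_order}
    for rec in screened_records:
        if rec.herb not in bioactive:
            herb_order.append(rec.herb)
            compounds.setdefault(rec.herb, set())
            bioactive[rec.herb] = set()
        bioactive[rec.herb].add(rec.mol_id)
    summaries: list[HerbSummary] = []
    for herb in herb_order:
        targets: set[str] = set()
        if target_map is not None:
            for mol in bioactive[herb]:
                targets |= target_map.get(mol, frozenset())
        summaries.append(
            HerbSummary(
                herb=herb,
                n_compounds=len(compounds[herb] | bioactive[herb]),
                n_bioactive=len(bioactive[herb]),
                n_targets=len(targets),
            )
        )
    return summaries
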