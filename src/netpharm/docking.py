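"""Docking score ingestion and ranking. Lower (more negative) energy wins."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DockingMatrix, NetpharmError, RowError


def read_docking_scores(path) -> DockingMatrix:
    """Read a binding-energy table, long or wide.

    Long format has columns (compound, target, energy); anything else is
    treated as a wide matrix with compound ids in the first column and
    target ids in the header.  Duplicate (compound, target) pairs keep the
    minimum (best) energy.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = [c.lower() for c in df.columns]
    if cols[:3] == ["compound", "target", "energy"]:
        pairs: dict[tuple[str, str], float] = {}
        for idx, row in df.iterrows():
            line = int(idx) + 2
            try:
                e = float(row.iloc[2])
            except ValueError:
                raise RowError(
                    f"non-numeric energy {row.iloc[2]!r}", line=line
                ) from None
            key = (str(row.iloc[0]).strip(), str(row.iloc[1]).strip())
            if key not in pairs or e < pairs[key]:
                pairs[key] = e
        compounds = sorted({c for c, _ in pairs})
        targets = sorted({t for _, t in pairs})
        mat = pd.DataFrame(np.nan, index=compounds, columns=targets)
        for (c, t), e in pairs.items():
            mat.loc[c, t] = e
        return DockingMatrix(energies=mat)
    # wide matrix
    mat = df.set_index(df.columns[0])
    try:
        mat = mat.apply(lambda s: s.map(lambda v: np.nan if v == "" else float(v)))
    except ValueError as exc:
        raise RowError(f"non-numeric energy in matrix: {exc}") from None
    mat.index.name = None
    return DockingMatrix(energies=mat)


def write_docking_long(m: DockingMatrix, path) -> None:
    rows = [
        {"compound": c, "target": t, "energy": m.energies.loc[c, t]}
        for c in m.compounds
        for t in m.proteins
        if not pd.isna(m.energies.loc[c, t])
    ]
    pd.DataFrame(rows, columns=["compound", "target", "energy"]).to_csv(
        path, sep="\t", index=False
    )


def rank_pairs(m: DockingMatrix, per: str = "global") -> list[tuple[str, str, float]]:
    """Rank (compound, target, energy) ascending by energy.

    ``per='target'`` returns each target's single best compound;
    ``per='compound'`` each compound's best target; ``per='global'`` the
    full ranking.  Ties break by compound label then target label.  Rows
    or columns that are entirely missing are excluded with a warning.
    """
    if m.is_empty():
        raise NetpharmError("docking matrix is empty")
    e = m.energies
    dead_rows = [c for c in e.index if e.loc[c].isna().all()]
    dead_cols = [t for t in e.columns if e[t].isna().all()]
    if dead_rows or dead_cols:
        warnings.warn(
            f"excluding all-missing rows {dead_rows} / columns {dead_cols}",
            stacklevel=2,
        )
    e = e.drop(index=dead_rows, columns=dead_cols)
    entries = [
        (float(e.loc[c, t]), c, t)
        for c in e.index
        for t in e.columns
        if not pd.isna(e.loc[c, t])
    ]
    entries.sort(key=lambda x: (x[0], x[1], x[2]))
    ranked = [(c, t, en) for en, c, t in entries]
    if per == "global":
        return ranked
    if per == "target":
        best: dict[str, tuple[str, str, float]] = {}
        for c, t, en in ranked:
            best.setdefault(t, (c, t, en))
        return [best[t] for t in sorted(best)]
    if per == "compound":
        best = {}
        for c, t, en in ranked:
            best.setdefault(c, (c, t, en))
        return [best[c] for c in sorted(best)]
    raise ValueError(f"unknown ranking mode {per!r}")


@dataclass
class SpontaneityReport:
    flagged: list[tuple[str, str, float]] = field(default_factory=list)
    per_compound: dict[str, int] = field(default_factory=dict)
    per_target: dict[str, int] = field(default_factory=dict)

    @property
    def n_flagged(self) -> int:
        return len(self.flagged)


def spontaneity_check(m: DockingMatrix) -> SpontaneityReport:
    """Flag non-negative energies (pairs not predicted to bind spontaneously)."""
    report = SpontaneityReport(
        per_compound={c: 0 for c in m.compounds},
        per_target={t: 0 for t in m.proteins},
    )
    for c in m.compounds:
        for t in m.proteins:
            e = m.energies.loc[c, t]
            if pd.isna(e):
                continue
            if e >= 0:
                report.flagged.append((c, t, float(e)))
                report.per_compound[c] += 1
                report.per_target[t] += 1
    return report


def heatmap_export(m: DockingMatrix, path) -> None:
    """Wide matrix export, compounds as rows, targets as columns."""
    out = m.energies.copy()
    out.index.name = "compound"
    out.to_csv(path, sep="\t")
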