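"""Domain types and readers/writers for the tables the pipeline touches.

All tabular inputs are tab-separated text with a header row.  Column names
vary between database exports, so every reader accepts a *dialect*: a map
from the canonical column name used here to the name actually present in
the file.  Gene symbols are case-normalized to uppercase before any set
operation, so symbol matching is deterministic regardless of the mixture
of gene and protein nomenclature found in source exports.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field

import pandas as pd


class NetpharmError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(NetpharmError):
    """A configuration problem: missing column, bad parameter, absent file."""


class RowError(NetpharmError):
    """A malformed row in an input table; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol. Raises on empty input."""
    s = str(symbol).strip().upper()
    if not s:
        raise ValueError("empty gene symbol")
    return s


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundRecord:
    """One herb-level compound listing with its screening attributes.

    ``ob`` is oral bioavailability as a percentage in [0, 100]; ``dl`` is
    the unitless drug-likeness index in [0, 1].  ``n_targets`` is the
    optional mapped-target count carried by some exports.
    """

    mol_id: str
    name: str
    ob: float
    dl: float
    herb: str
    n_targets: int | None = None

    def __post_init__(self) -> None:
        if not self.mol_id:
            raise ValueError("mol_id must be non-empty")
        if not 0.0 <= self.ob <= 100.0:
            raise ValueError(f"ob out of [0, 100]: {self.ob!r} ({self.mol_id})")
        if not 0.0 <= self.dl <= 1.0:
            raise ValueError(f"dl out of [0, 1]: {self.dl!r} ({self.mol_id})")
        if self.n_targets is not None and self.n_targets < 0:
            raise ValueError(f"n_targets must be >= 0 ({self.mol_id})")


@dataclass(frozen=True)
class HerbSummary:
    """Per-herb compound/bioactive/target counts."""

    herb: str
    n_compounds: int
    n_bioactive: int
    n_targets: int

    def __post_init__(self) -> None:
        if min(self.n_compounds, self.n_bioactive, self.n_targets) < 0:
            raise ValueError(f"negative count for herb {self.herb!r}")
        if self.n_bioactive > self.n_compounds:
            raise ValueError(
                f"n_bioactive > n_compounds for herb {self.herb!r}"
            )


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols, case-normalized at construction."""

    label: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        normalized = frozenset(normalize_symbol(g) for g in self.genes)
        object.__setattr__(self, "genes", normalized)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return normalize_symbol(gene) in self.genes

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.genes))


class TargetMap(Mapping[str, frozenset[str]]):
    """Mapping from compound id to its set of target gene symbols.

    Symbols are normalized and deduplicated; empty symbols are rejected.
    """

    def __init__(self, mapping: Mapping[str, Iterable[str]] | None = None):
        self._map: dict[str, frozenset[str]] = {}
        if mapping:
            for mol_id, genes in mapping.items():
                self._map[str(mol_id)] = frozenset(
                    normalize_symbol(g) for g in genes
                )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "TargetMap":
        acc: dict[str, set[str]] = {}
        for mol_id, gene in pairs:
            acc.setdefault(str(mol_id), set()).add(normalize_symbol(gene))
        return cls(acc)

    def __getitem__(self, mol_id: str) -> frozenset[str]:
        return self._map[mol_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self._map)

    def __len__(self) -> int:
        return len(self._map)

    def restrict(self, genes: GeneSet | Iterable[str]) -> "TargetMap":
        """Keep only targets inside ``genes``; compounds may end up empty."""
        keep = (
            genes.genes
            if isinstance(genes, GeneSet)
            else frozenset(normalize_symbol(g) for g in genes)
        )
        return TargetMap({m: ts & keep for m, ts in self._map.items()})

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for ts in self._map.values():
            out |= ts
        return frozenset(out)


@dataclass
class DockingMatrix:
    """Compound x protein binding-energy matrix in kcal/mol.

    Missing cells are NaN, never silently zero.
    """

    energies: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def compounds(self) -> list[str]:
        return list(self.energies.index)

    @property
    def proteins(self) -> list[str]:
        return list(self.energies.columns)

    def is_empty(self) -> bool:
        return self.energies.size == 0 or self.energies.isna().all().all()


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

COMPOUND_COLUMNS = ("mol_id", "name", "ob", "dl", "herb")
HERB_SEPARATOR = "|"


def _resolve_columns(
    df: pd.DataFrame,
    required: Iterable[str],
    dialect: Mapping[str, str] | None,
) -> dict[str, str]:
    dialect = dict(dialect or {})
    resolved: dict[str, str] = {}
    for canonical in required:
        actual = dialect.get(canonical, canonical)
        if actual not in df.columns:
            raise ConfigError(
                f"required column {canonical!r} (file column {actual!r}) "
                f"not found; available: {list(df.columns)}"
            )
        resolved[canonical] = actual
    return resolved


def _parse_float(value: str, column: str, line: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise RowError(f"unparseable {column} value {value!r}", line=line) from None


def read_compound_table(
    path, dialect: Mapping[str, str] | None = None
) -> list[CompoundRecord]:
    """Read a compound table into herb-expanded :class:`CompoundRecord` rows.

    A row whose herb field lists several herbs (separated by ``|``) is
    expanded into one record per herb, all sharing the compound's mol_id,
    ob and dl.  The optional ``n_targets`` column is carried through when
    present.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(df, COMPOUND_COLUMNS, dialect)
    nt_col = (dialect or {}).get("n_targets", "n_targets")
    has_nt = nt_col in df.columns

    records: list[CompoundRecord] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        ob = _parse_float(row[cols["ob"]], "ob", line)
        dl = _parse_float(row[cols["dl"]], "dl", line)
        n_targets: int | None = None
        if has_nt and str(row[nt_col]).strip():
            n_targets = int(_parse_float(row[nt_col], "n_targets", line))
        herbs = [h.strip() for h in str(row[cols["herb"]]).split(HERB_SEPARATOR)]
        herbs = [h for h in herbs if h]
        if not herbs:
            raise RowError("no herb listed", line=line)
        for herb in herbs:
            try:
                records.append(
                    CompoundRecord(
                        mol_id=str(row[cols["mol_id"]]).strip(),
                        name=str(row[cols["name"]]).strip(),
                        ob=ob,
                        dl=dl,
                        herb=herb,
                        n_targets=n_targets,
                    )
                )
            except ValueError as exc:
                raise RowError(str(exc), line=line) from None
    return records


def write_compound_table(records: Iterable[CompoundRecord], path) -> None:
    """Write records in long form, one (compound, herb) row each."""
    rows = [
        {
            "mol_id": r.mol_id,
            "name": r.name,
            "ob": r.ob,
            "dl": r.dl,
            "herb": r.herb,
            "n_targets": "" if r.n_targets is None else r.n_targets,
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["mol_id", "name", "ob", "dl", "herb", "n_targets"]
    ).to_csv(path, sep="\t", index=False)


def read_gene_list(path, label: str | None = None, source: str = "") -> GeneSet:
    """Read a one-symbol-per-line gene list; blank lines are ignored."""
    genes: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            token = raw.strip()
            if token:
                genes.add(normalize_symbol(token))
    if not genes:
        warnings.warn(f"gene list {path} is empty", stacklevel=2)
    name = label if label is not None else str(path)
    return GeneSet(label=name, genes=frozenset(genes), source=source)


def write_gene_list(genes: GeneSet | Iterable[str], path) -> None:
    symbols = genes.genes if isinstance(genes, GeneSet) else set(genes)
    with open(path, "w") as fh:
        for g in sorted(normalize_symbol(s) for s in symbols):
            fh.write(g + "\n")


def read_gmt(path, source: str = "") -> list[GeneSet]:
    """Read a GMT gene-set collection: name<TAB>description<TAB>genes..."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise RowError(
                    f"GMT line needs >= 3 tab-separated fields, got {len(fields)}",
                    line=lineno,
                )
            name, _desc, *genes = fields
            members = frozenset(
                normalize_symbol(g) for g in genes if g.strip()
            )
            sets.append(GeneSet(label=name, genes=members, source=source))
    return sets


def write_gmt(sets: Iterable[GeneSet], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.label, description, *sorted(gs.genes)]) + "\n")


def read_target_map(path, dialect: Mapping[str, str] | None = None) -> TargetMap:
    """Read a compound->target table (columns ``mol_id``, ``gene``).

    The gene field may hold several symbols separated by ``|``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(df, ("mol_id", "gene"), dialect)
    pairs: list[tuple[str, str]] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2
        mol = str(row[cols["mol_id"]]).strip()
        if not mol:
            raise RowError("empty mol_id", line=line)
        for g in str(row[cols["gene"]]).split(HERB_SEPARATOR):
            if g.strip():
                pairs.append((mol, g))
    return TargetMap.from_pairs(pairs)


def write_target_map(tmap: TargetMap, path) -> None:
    rows = [
        {"mol_id": mol, "gene": gene}
        for mol in sorted(tmap)
        for gene in sorted(tmap[mol])
    ]
    pd.DataFrame(rows, columns=["mol_id", "gene"]).to_csv(
        path, sep="\t", index=False
    )
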