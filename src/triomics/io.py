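"""Readers/writers for the on-disk formats plus small QC arithmetic.

All tables are tab-separated UTF-8 with '.' as the decimal separator, the
dialect common to omics exports. Gene sets use the standard GMT layout
(set name, description, then one member per tab-separated field).

The central in-memory container is :class:`ExpressionMatrix`: a features x
samples abundance block (FPKM-like for transcripts, reporter-intensity-like
for proteins) with a fresh/frozen group label per sample.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import AlignmentError, DomainError, FormatError

GROUP_FRESH = "FS"
GROUP_FROZEN = "PS"
VALID_GROUPS = (GROUP_FRESH, GROUP_FROZEN)

# Phenotype columns constrained to the unit interval x 100 (percentages)
# versus non-negative velocities/amplitudes, mirroring CASA output.
_PERCENT_COLUMNS = ("motility", "viability")


@dataclass
class ExpressionMatrix:
    """Features x samples abundance block with per-sample group labels.

    Parameters
    ----------
    data:
        ``pandas.DataFrame`` indexed by feature id with one column per
        sample. Values must be finite and non-negative (abundances).
    groups:
        Mapping/Series from sample id to ``"FS"`` (fresh) or ``"PS"``
        (programmed freezing). Every sample needs a label.
    unit:
        Free-text unit recorded as metadata (e.g. ``"FPKM"``,
        ``"reporter_intensity"``); the statistics downstream are
        unit-agnostic.
    """

    data: pd.DataFrame
    groups: pd.Series
    unit: str = "abundance"

    def __post_init__(self) -> None:
        if not isinstance(self.groups, pd.Series):
            self.groups = pd.Series(dict(self.groups))
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dupes = sorted(set(idx[idx.duplicated()]))
            raise FormatError(f"duplicate feature id(s): {dupes}")
        if cols.duplicated().any():
            dupes = sorted(set(cols[cols.duplicated()]))
            raise FormatError(f"duplicate sample id(s): {dupes}")
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.isfinite(vals).all():
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise FormatError(
                f"non-finite value at feature {idx[r]!r}, sample {cols[c]!r}"
            )
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise FormatError(
                f"negative abundance at feature {idx[r]!r}, sample {cols[c]!r}"
            )
        missing = [s for s in cols if s not in self.groups.index]
        if missing:
            raise FormatError(f"samples without a group label: {missing}")
        bad = sorted(set(self.groups.loc[list(cols)]) - set(VALID_GROUPS))
        if bad:
            raise FormatError(
                f"unknown group label(s) {bad}; expected one of {VALID_GROUPS}"
            )
        self.groups = self.groups.loc[list(cols)]

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.data.columns if self.groups[s] == group]

    def group_data(self, group: str) -> pd.DataFrame:
        return self.data[self.samples_in_group(group)]

    def subset(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        keep = [f for f in feature_ids if f in self.data.index]
        return ExpressionMatrix(self.data.loc[keep], self.groups.copy(), self.unit)

    def log2(self, eps: float = 1e-3) -> pd.DataFrame:
        """log2-transformed abundances with pseudocount ``eps``."""
        if eps <= 0:
            raise DomainError("eps must be > 0")
        return np.log2(self.data + eps)


@dataclass
class IdMap:
    """Symmetric gene <-> protein identifier map.

    Lookups are case-insensitive (gene symbols appear in mixed case across
    sources) but the original spelling is preserved in outputs.
    """

    pairs: list[tuple[str, str]]
    _g2p: dict[str, list[str]] = field(init=False, repr=False)
    _p2g: dict[str, list[str]] = field(init=False, repr=False)
    _gene_case: dict[str, str] = field(init=False, repr=False)
    _protein_case: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        self._g2p, self._p2g = {}, {}
        self._gene_case, self._protein_case = {}, {}
        for g, p in self.pairs:
            key = (g.casefold(), p.casefold())
            if key in seen:
                raise FormatError(f"duplicated id-map pair ({g}, {p})")
            seen.add(key)
            self._g2p.setdefault(key[0], []).append(p)
            self._p2g.setdefault(key[1], []).append(g)
            self._gene_case.setdefault(key[0], g)
            self._protein_case.setdefault(key[1], p)

    def proteins_for(self, gene_id: str) -> list[str]:
        return list(self._g2p.get(gene_id.casefold(), []))

    def genes_for(self, protein_id: str) -> list[str]:
        return list(self._p2g.get(protein_id.casefold(), []))

    def has_gene(self, gene_id: str) -> bool:
        return gene_id.casefold() in self._g2p

    def has_protein(self, protein_id: str) -> bool:
        return protein_id.casefold() in self._p2g

    def to_gene_space(
        self, feature_ids: Iterable[str]
    ) -> tuple[set[str], list[str]]:
        """Map a mixed gene/protein id collection onto gene ids.

        Ids that already look like mapped genes pass through; protein ids
        are translated; anything unmappable is returned in the dropped list
        rather than raising — real annotation tables are always incomplete.
        """
        mapped: set[str] = set()
        dropped: list[str] = []
        for fid in feature_ids:
            cf = fid.casefold()
            if cf in self._g2p:
                mapped.add(self._gene_case[cf])
            elif cf in self._p2g:
                mapped.update(self._p2g[cf])
            else:
                dropped.append(fid)
        return mapped, dropped


@dataclass
class GeneSetCollection:
    """Named feature sets, GMT-style: name -> (description, members)."""

    sets: dict[str, tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        for name, (_desc, members) in self.sets.items():
            if len(members) == 0:
                raise FormatError(f"gene set {name!r} has no members")

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class PhenotypeTable:
    """Per-sample sperm-quality phenotypes (CASA-style).

    Percentages (motility, viability) must lie in [0, 100]; velocity and
    amplitude columns must be non-negative.
    """

    data: pd.DataFrame  # samples x phenotype columns

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise FormatError("duplicate sample ids in phenotype table")
        for col in self.data.columns:
            vals = self.data[col].to_numpy(dtype=float)
            if not np.isfinite(vals).all():
                raise FormatError(f"non-finite phenotype values in {col!r}")
            if col.lower() in _PERCENT_COLUMNS:
                if ((vals < 0) | (vals > 100)).any():
                    raise FormatError(f"{col!r} must lie in [0, 100]")
            elif (vals < 0).any():
                raise FormatError(f"{col!r} must be non-negative")

    def column(self, name: str) -> pd.Series:
        return self.data[name]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_group_spec(spec: Mapping[str, str] | str | Path) -> pd.Series:
    """Accept either an in-memory mapping or a two-column TSV (sample, group)."""
    if isinstance(spec, (str, Path)):
        df = pd.read_csv(spec, sep="\t", header=None, names=["sample", "group"],
                         dtype=str, comment="#")
        if df["sample"].duplicated().any():
            raise FormatError("duplicate sample ids in group spec")
        return pd.Series(df["group"].to_numpy(), index=df["sample"])
    return pd.Series(dict(spec))


def read_expression_matrix(
    path: str | Path,
    group_spec: Mapping[str, str] | str | Path,
    unit: str = "abundance",
    drop_incomplete: bool = False,
) -> ExpressionMatrix:
    """Read a feature x sample TSV (first column = feature id, header = samples).

    Missing values are rejected (the downstream statistics assume complete
    blocks); pass ``drop_incomplete=True`` to drop rows with missing cells
    instead.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    non_numeric = [c for c in df.columns
                   if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        for c in non_numeric:
            bad = df[pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()]
            if len(bad):
                raise FormatError(
                    f"non-numeric cell at feature {bad.index[0]!r}, sample {c!r}"
                )
        df = df.apply(pd.to_numeric)
    if df.isna().any().any():
        if drop_incomplete:
            df = df.dropna(axis=0)
        else:
            r = df.index[df.isna().any(axis=1)][0]
            c = df.columns[df.loc[r].isna()][0]
            raise FormatError(
                f"missing value at feature {r!r}, sample {c!r} "
                "(pass drop_incomplete=True to drop such rows)"
            )
    groups = read_group_spec(group_spec)
    return ExpressionMatrix(df, groups, unit=unit)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="feature_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"GMT line {lineno}: set {name!r} is empty")
            if name in sets:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = (desc, tuple(members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in collection.names():
            desc = collection.description(name)
            members = "\t".join(collection.members(name))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_id_map(path: str | Path) -> IdMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns)[:2] != ["gene_id", "protein_id"]:
        # tolerate headerless two-column files
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["gene_id", "protein_id"], dtype=str)
    if df.shape[1] < 2:
        raise FormatError("id map must have two columns: gene_id, protein_id")
    return IdMap(list(zip(df["gene_id"], df["protein_id"])))


def write_id_map(id_map: IdMap, path: str | Path) -> None:
    pd.DataFrame(id_map.pairs, columns=["gene_id", "protein_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_phenotype(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return PhenotypeTable(df)


def write_phenotype(table: PhenotypeTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def align_samples(a: ExpressionMatrix, b: ExpressionMatrix) -> None:
    """Raise unless both matrices carry the same samples in the same order."""
    if a.sample_ids != b.sample_ids:
        raise AlignmentError(
            "sample mismatch between paired matrices: "
            f"{a.sample_ids} vs {b.sample_ids}"
        )


# ---------------------------------------------------------------------------
# QC arithmetic
# ---------------------------------------------------------------------------


def mapping_rate(total_reads: int, unique_mapped: int) -> float:
    """Unique-mapping percentage, half-up rounded to two decimals.

    The published convention rounds half away from zero (e.g. a run with
    186,669,343 uniquely mapped of 310,699,628 total reads maps at 60.08%).
    """
    if total_reads <= 0:
        raise DomainError("total_reads must be positive")
    if not 0 <= unique_mapped <= total_reads:
        raise DomainError("unique_mapped must lie in [0, total_reads]")
    pct = decimal.Decimal(100 * unique_mapped) / decimal.Decimal(total_reads)
    return float(pct.quantize(decimal.Decimal("0.01"),
                              rounding=decimal.ROUND_HALF_UP))
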