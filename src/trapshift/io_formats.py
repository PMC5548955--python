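"""Readers, writers and validated in-memory containers for every file the
pipeline touches.

All tabular formats are plain TSV. Gene identifiers are opaque strings: no
species or annotation scheme is assumed. Gene sets use the GMT exchange
format (name, description, then one gene per column). Clan membership is a
two-column ``gene_id\tclan_id`` multimap, so one gene may carry several
clans and most genes carry none.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

FRACTIONS = ("IP", "Input")
GENOTYPES = ("WT", "KO")

_FRACTION_ALIASES = {"ip": "IP", "input": "Input"}
_GENOTYPE_ALIASES = {"wt": "WT", "ko": "KO"}

SAMPLE_SHEET_COLUMNS = ["sample_id", "fraction", "genotype", "pair_id", "animal_id"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts.

    ``counts`` is a DataFrame indexed by gene id with sample ids as columns;
    both axes must be duplicate-free and every entry a non-negative integer.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r} in count matrix")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r} in count matrix")
        values = self.counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                raise FormatError("count matrix contains non-numeric entries")
            if np.issubdtype(values.dtype, np.floating):
                if not np.all(np.isfinite(values)):
                    raise FormatError("count matrix contains non-finite entries")
                if np.any(values != np.floor(values)):
                    g, s = np.argwhere(values != np.floor(values))[0]
                    raise FormatError(
                        f"non-integer count for gene {idx[g]!r}, sample {cols[s]!r}"
                    )
            if np.any(values < 0):
                g, s = np.argwhere(values < 0)[0]
                raise FormatError(
                    f"negative count for gene {idx[g]!r}, sample {cols[s]!r}"
                )
            self.counts = self.counts.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_samples(self, sample_ids) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise ValidationError(f"samples not in count matrix: {missing}")
        return CountMatrix(self.counts[list(sample_ids)].copy())


@dataclass
class SampleSheet:
    """Per-sample annotations: fraction (IP/Input), genotype (WT/KO), littermate pair.

    Each littermate pair contributes one WT and one KO animal; every animal
    has at most one IP and one Input library.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        t = t[SAMPLE_SHEET_COLUMNS].copy()
        t["fraction"] = [_normalize_token(v, _FRACTION_ALIASES, "fraction") for v in t["fraction"]]
        t["genotype"] = [_normalize_token(v, _GENOTYPE_ALIASES, "genotype") for v in t["genotype"]]
        try:
            t["pair_id"] = t["pair_id"].astype(int)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-integer pair_id in sample sheet: {exc}") from exc
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample_id {dup!r} in sample sheet")
        counts = t.groupby(["pair_id", "genotype", "fraction"]).size()
        bad = counts[counts > 1]
        if len(bad):
            key = bad.index[0]
            raise ValidationError(
                f"more than one {key[2]} sample for pair {key[0]} genotype {key[1]}"
            )
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def subset(self, fraction: str | None = None, genotype: str | None = None) -> "SampleSheet":
        t = self.table
        if fraction is not None:
            fraction = _normalize_token(fraction, _FRACTION_ALIASES, "fraction")
            t = t[t["fraction"] == fraction]
        if genotype is not None:
            genotype = _normalize_token(genotype, _GENOTYPE_ALIASES, "genotype")
            t = t[t["genotype"] == genotype]
        return SampleSheet(t.reset_index(drop=True))

    @property
    def n_pairs(self) -> int:
        return self.table["pair_id"].nunique()


@dataclass(frozen=True)
class GeneSet:
    """A named, duplicate-free, non-empty collection of gene ids."""

    name: str
    description: str
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ClanMap:
    """Multimap gene id -> set of clan ids; unannotated genes map to the empty set."""

    mapping: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for gene, clans in self.mapping.items():
            clans = frozenset(clans)
            if any(not c for c in clans):
                raise ValidationError(f"empty clan id for gene {gene!r}")
            if clans:
                clean[gene] = clans
        self.mapping = clean

    def __getitem__(self, gene: str) -> frozenset[str]:
        return self.mapping.get(gene, frozenset())

    def __len__(self) -> int:
        return len(self.mapping)

    def __eq__(self, other) -> bool:
        return isinstance(other, ClanMap) and self.mapping == other.mapping

    def clans(self) -> frozenset[str]:
        out: set[str] = set()
        for clans in self.mapping.values():
            out |= clans
        return frozenset(out)

    def genes_in_clan(self, clan: str) -> frozenset[str]:
        return frozenset(g for g, cs in self.mapping.items() if clan in cs)


def _normalize_token(value, aliases: dict[str, str], what: str) -> str:
    key = str(value).strip().lower()
    if key not in aliases:
        raise ValidationError(
            f"unknown {what} token {value!r}; expected one of {sorted(set(aliases.values()))}"
        )
    return aliases[key]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_counts(path, sample_sheet: SampleSheet | None = None) -> CountMatrix:
    """Read a gene x sample TSV of integer counts.

    The first column holds gene ids, the header row sample ids. When a
    sample sheet is given, columns are reordered to the sheet order and every
    sheet sample must be present in the file.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise FormatError(f"cannot parse count file {path}: {exc}") from exc
    if df.isna().to_numpy().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise FormatError(f"missing value in counts for gene {gene!r}; zeros must be explicit")
    cm = CountMatrix(df)
    if sample_sheet is not None:
        missing = [s for s in sample_sheet.sample_ids if s not in df.columns]
        if missing:
            raise ValidationError(f"samples in sheet but not in count file: {missing}")
        cm = cm.subset_samples(sample_sheet.sample_ids)
    return cm


def write_counts(cm: CountMatrix, path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path) -> SampleSheet:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot parse sample sheet {path}: {exc}") from exc
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: one tab-separated line per set (name, description, genes...).

    Duplicate genes within one line are dropped with a logged warning.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]
            if len(set(genes)) != len(genes):
                logger.warning("%s:%d: duplicate genes in set %r deduplicated", path, lineno, name)
            sets.append(GeneSet(name=name, description=description, genes=frozenset(genes)))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.genes)]) + "\n")


def read_clan_map(path) -> ClanMap:
    """Read a two-column ``gene_id\tclan_id`` TSV; repeated gene rows accumulate."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated fields")
            mapping.setdefault(fields[0], set()).add(fields[1])
    return ClanMap({g: frozenset(c) for g, c in mapping.items()})


def write_clan_map(clan_map: ClanMap, path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(clan_map.mapping):
            for clan in sorted(clan_map.mapping[gene]):
                fh.write(f"{gene}\t{clan}\n")


def read_lengths(path) -> pd.Series:
    """Read a two-column ``gene_id\teffective_length`` TSV of positive lengths (bases)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "length"], dtype={0: str})
    except Exception as exc:
        raise FormatError(f"cannot parse lengths file {path}: {exc}") from exc
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"duplicate gene id {dup!r} in lengths file")
    lengths = pd.Series(df["length"].to_numpy(dtype=float), index=df["gene_id"])
    if not np.all(np.isfinite(lengths)) or np.any(lengths <= 0):
        gene = lengths.index[~(np.isfinite(lengths) & (lengths > 0))][0]
        raise ValidationError(f"non-positive length for gene {gene!r}")
    return lengths


def write_lengths(lengths: pd.Series, path) -> None:
    lengths.to_csv(path, sep="\t", header=False)


def write_results(table: pd.DataFrame, path, index_label: str = "gene_id") -> None:
    """Write a results table as TSV with stable column order and 'NA' for missing."""
    table.to_csv(path, sep="\t", na_rep="NA", index_label=index_label)
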