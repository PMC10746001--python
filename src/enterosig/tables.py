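"""Taxon-abundance tables: container, taxonomy aggregation, and TSV I/O.

The central container is :class:`AbundanceTable`, an integer count matrix
(taxa x samples) together with one taxonomic lineage string per taxon and a
tag for the taxonomic level the rows represent.  Lineage strings use the
conventional greengenes-style prefixes (``k__Bacteria;p__Firmicutes;...``);
a rank whose name is missing or ``?`` counts as unresolved at that rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_PREFIX_TO_RANK = {r[0]: r for r in RANKS}
# 'class' uses c__ like 'class'; no clash because prefixes are unique initials

LEVELS = ("otu", "phylum", "genus")


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse ``k__...;p__...;g__...`` into {rank: name}, dropping unresolved ranks.

    A field is unresolved when its name part is empty, ``?`` or starts with
    ``uncl``.  Fields without a recognised prefix are ignored.
    """
    out: dict[str, str] = {}
    for part in str(lineage).split(";"):
        part = part.strip()
        if len(part) >= 3 and part[1:3] == "__" and part[0] in _PREFIX_TO_RANK:
            name = part[3:].strip()
            if name and name != "?" and not name.lower().startswith("uncl"):
                out[_PREFIX_TO_RANK[part[0]]] = name
    return out


def _resolve_at_rank(lineage: str, rank: str) -> str:
    """Label for a lineage at `rank`; pooled as ``uncl. <ancestor>`` when unresolved."""
    parsed = parse_lineage(lineage)
    if rank in parsed:
        return parsed[rank]
    # fall back to the nearest resolvable ancestor rank
    idx = RANKS.index(rank)
    for anc in reversed(RANKS[:idx]):
        if anc in parsed:
            return f"uncl. {parsed[anc]}"
    return "unassigned"


@dataclass
class AbundanceTable:
    """Integer count matrix (rows = taxa, columns = samples) with lineages.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame, index = taxon ids, columns = sample ids.
    lineages
        Lineage string per taxon, aligned with ``counts.index``.
    level
        One of ``otu``, ``phylum``, ``genus``.
    """

    counts: pd.DataFrame
    lineages: pd.Series
    level: str = "otu"

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}; expected one of {LEVELS}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts are not allowed")
        if self.counts.columns.duplicated().any():
            raise ValueError("sample ids must be unique")
        self.lineages = pd.Series(self.lineages).reindex(self.counts.index)
        if self.lineages.isna().any():
            missing = list(self.lineages.index[self.lineages.isna()])
            raise ValueError(f"taxa without lineage: {missing[:5]}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions (columns sum to 1)."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            empty = list(totals.index[totals == 0])
            raise ValueError(f"samples with zero total counts: {empty}")
        return self.counts / totals

    def copy(self) -> "AbundanceTable":
        return replace(self, counts=self.counts.copy(), lineages=self.lineages.copy())


def aggregate(table: AbundanceTable, level: str) -> AbundanceTable:
    """Sum counts into one row per taxon at `level` (phylum or genus).

    Lineages that do not resolve at the requested rank are pooled into an
    ``uncl. <nearest resolvable ancestor>`` row; lineages with no resolvable
    ancestor at all go into an ``unassigned`` row (with a warning).  Column
    totals are preserved exactly.
    """
    if level not in ("phylum", "genus"):
        raise ValueError(f"aggregation level must be phylum or genus, got {level!r}")
    if table.level == level:
        return table

    labels = table.lineages.map(lambda s: _resolve_at_rank(s, level))
    if (labels == "unassigned").any():
        n_bad = int((labels == "unassigned").sum())
        warnings.warn(
            f"{n_bad} taxa had no resolvable rank at or above {level}; "
            "pooled into 'unassigned'",
            stacklevel=2,
        )
    agg = table.counts.groupby(labels.values).sum()
    prefix = level[0]
    lineages = pd.Series(
        {
            name: name if name.startswith(("uncl.", "unassigned")) else f"{prefix}__{name}"
            for name in agg.index
        }
    )
    return AbundanceTable(counts=agg, lineages=lineages, level=level)


def fb_ratio(
    table: AbundanceTable, groups: pd.Series | None = None
) -> dict:
    """Firmicutes/Bacteroidetes relative-abundance ratio per sample.

    Parameters
    ----------
    table
        A phylum-level abundance table containing both phyla.
    groups
        Optional sample -> group labels; when given, per-group mean +/- SEM and
        pairwise percent changes between group means are reported.

    Returns
    -------
    dict with keys ``per_sample`` (Series), and when groups are given
    ``summary`` (DataFrame mean/sem/n per group) and ``contrasts``
    (DataFrame of percent change of each group mean vs. every other).
    """
    if table.level != "phylum":
        table = aggregate(table, "phylum")
    rel = table.relative_abundance()

    def _row(name: str) -> pd.Series:
        hits = [t for t in rel.index if t == name]
        if not hits:
            raise ValueError(f"phylum {name!r} absent from table")
        return rel.loc[name]

    firm = _row("Firmicutes")
    bact = _row("Bacteroidetes")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = firm / bact
    zero_b = bact == 0
    if zero_b.any():
        warnings.warn(
            f"Bacteroidetes absent in {int(zero_b.sum())} sample(s); "
            "F/B ratio reported missing there",
            stacklevel=2,
        )
        ratio = ratio.mask(zero_b)
    out: dict = {"per_sample": ratio.rename("fb_ratio")}
    if groups is not None:
        groups = pd.Series(groups).reindex(ratio.index)
        gb = ratio.groupby(groups.values)
        summary = pd.DataFrame(
            {"mean": gb.mean(), "sem": gb.sem(), "n": gb.count()}
        )
        rows = []
        means = summary["mean"]
        for g1 in means.index:
            for g2 in means.index:
                if g1 != g2:
                    rows.append(
                        {
                            "group": g1,
                            "reference": g2,
                            "pct_change": 100.0 * (means[g1] - means[g2]) / means[g2],
                        }
                    )
        out["summary"] = summary
        out["contrasts"] = pd.DataFrame(rows)
    return out


# ---------------------------------------------------------------------------
# TSV I/O.  Writers emit '#'-prefixed provenance header lines; readers skip
# any number of leading comment lines.

def write_abundance_tsv(table: AbundanceTable, path, header_note: str = "") -> None:
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        fh.write(f"# level={table.level}\n")
        df = table.counts.copy()
        df.insert(0, "lineage", table.lineages.values)
        df.index.name = "taxon"
        df.to_csv(fh, sep="\t")


def read_abundance_tsv(path) -> AbundanceTable:
    level = "otu"
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if "level=" in line:
                level = line.split("level=")[1].strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    lineages = df.pop("lineage")
    counts = df.astype(np.int64)
    counts.index.name = None
    lineages.index.name = None
    return AbundanceTable(counts=counts, lineages=lineages, level=level)


def write_metadata_tsv(meta: pd.DataFrame, path, header_note: str = "") -> None:
    with open(path, "w") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        meta.to_csv(fh, sep="\t", index=False)


def read_metadata_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
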