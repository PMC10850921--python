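"""Plastid types: maternal lineages from multi-locus genotype vectors.

Accessions sharing an identical allele-code vector across the marker
panel form one plastid type. Published lineage tallies for this system
additionally keep accessions from different collection regions apart, so
grouping can optionally be stratified by extra metadata columns; the
default is the pure genotype-vector partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class PlastidType:
    """A maternal lineage: one genotype vector and its member accessions."""

    label: str
    genotype_vector: tuple
    members: list[str]
    strata: tuple = ()

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class TypeAssignment:
    """Result of a typing run: the types plus accessions excluded for
    missing calls."""

    types: list[PlastidType]
    excluded: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.types)

    def membership(self) -> dict[str, str]:
        return {acc: t.label for t in self.types for acc in t.members}


def assign_plastid_types(
    genotypes: pd.DataFrame,
    panel: list[str],
    stratify_by: tuple[str, ...] = (),
    alias: dict[tuple, str] | None = None,
) -> TypeAssignment:
    """Partition accessions into plastid types by their panel vectors.

    `genotypes` is indexed by accession (or has an 'accession' column)
    with one column per panel locus; accessions missing any panel call
    are excluded and reported. Types are labelled T01, T02, ... in
    lexicographic vector order (deterministic and independent of row
    order); `alias` can rename them by vector. With `stratify_by`,
    accessions are additionally split by those metadata columns — the
    convention used by the published lineage tally, which separates
    regions.
    """
    if not panel:
        raise ValueError("empty marker panel")
    df = genotypes.reset_index() if genotypes.index.name == "accession" \
        else genotypes.copy()
    if "accession" not in df.columns:
        raise ValueError("genotype table needs an 'accession' column or index")
    missing = [c for c in list(panel) + list(stratify_by)
               if c not in df.columns]
    if missing:
        raise ValueError(f"genotype table lacks columns {missing}")

    ok = df[list(panel)].notna().all(axis=1)
    excluded = sorted(df.loc[~ok, "accession"])
    df = df.loc[ok]

    keys = {}
    for _, row in df.iterrows():
        vector = tuple(int(row[c]) for c in panel)
        strata = tuple(row[c] for c in stratify_by)
        keys.setdefault((vector, strata), []).append(row["accession"])

    types = []
    for i, (vector, strata) in enumerate(sorted(keys), start=1):
        label = (alias or {}).get(vector, f"T{i:02d}")
        types.append(PlastidType(label, vector, sorted(keys[(vector, strata)]),
                                 strata))
    return TypeAssignment(types, excluded)


def tally_types_by_taxon(assignment: TypeAssignment,
                         metadata: pd.DataFrame) -> pd.DataFrame:
    """Contingency table of plastid types (rows) by taxon (columns).

    `metadata` maps accession -> species (and optionally region); every
    type member must be present in it. Marginals are appended as a
    'total' row and column.
    """
    meta = metadata.set_index("accession") if "accession" in metadata.columns \
        else metadata
    counts: dict[str, dict[str, int]] = {}
    for t in assignment.types:
        row: dict[str, int] = {}
        for acc in t.members:
            if acc not in meta.index:
                raise KeyError(f"accession {acc!r} absent from metadata")
            sp = meta.loc[acc, "species"]
            row[sp] = row.get(sp, 0) + 1
        counts[t.label] = row
    table = pd.DataFrame(counts).T.fillna(0).astype(int)
    table = table.sort_index()
    table.loc["total"] = table.sum()
    table["total"] = table.sum(axis=1)
    table.index.name = "plastid_type"
    return table


def shared_types(tally: pd.DataFrame) -> pd.DataFrame:
    """Types observed in two or more taxa, with their member taxa,
    sorted by type label."""
    body = tally.drop(index="total", columns="total", errors="ignore")
    rows = []
    for label, row in body.iterrows():
        taxa = [c for c in body.columns if row[c] > 0]
        if len(taxa) >= 2:
            rows.append((label, taxa))
    return pd.DataFrame(rows, columns=["plastid_type", "taxa"]).sort_values(
        "plastid_type", kind="stable").reset_index(drop=True)


def type_report_text(assignment: TypeAssignment,
                     tally: pd.DataFrame | None = None) -> str:
    """Plain-text report: label, vector, size (and per-taxon counts)."""
    lines = ["label\tvector\tn_members\tstrata"]
    for t in assignment.types:
        vec = ",".join(str(v) for v in t.genotype_vector)
        lines.append(f"{t.label}\t{vec}\t{t.size}\t"
                     f"{'/'.join(map(str, t.strata)) or '.'}")
    if assignment.excluded:
        lines.append(f"# excluded (missing calls): "
                     f"{','.join(assignment.excluded)}")
    if tally is not None:
        lines.append("")
        lines.append(tally.to_csv(sep="\t").rstrip())
    return "\n".join(lines) + "\n"
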